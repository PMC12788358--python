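"""Band-limited Gaussian functional connectivity (GFC).

For each trial and frequency band, every channel is reduced to its
band-limited spectral reconstruction (real FFT, bins inside the band
kept, inverse FFT).  Pairwise channel similarity is then measured with a
Gaussian kernel

    K[c, c'] = exp(-||x_c - x_c'||^2 / (2 sigma^2)),

where ``sigma`` defaults to the median of the pairwise Euclidean
distances between the band-limited channel signals (median heuristic,
computed per trial per band).  The C x C matrix is compressed to a
per-channel "flow" vector, the mean coupling of each channel with the
others, and flow vectors are min-max normalized channel-wise over a
training set before image rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "GFCMatrix",
    "FlowVector",
    "MinMaxNormalizer",
    "band_reconstruct",
    "gaussian_kernel",
    "gfc_matrix",
    "flow_vector",
    "fit_minmax",
    "apply_minmax",
    "trial_flows",
    "trialset_flows",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")


# The four sensorimotor rhythms; the upper two deliberately overlap.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("mu", 8.0, 12.0),
    BandSpec("beta_low", 12.0, 15.0),
    BandSpec("beta_mid", 15.0, 20.0),
    BandSpec("beta_high", 18.0, 40.0),
)


@dataclass
class GFCMatrix:
    K: np.ndarray
    band: BandSpec
    sigma: float


@dataclass
class FlowVector:
    g: np.ndarray
    band: BandSpec


@dataclass
class MinMaxNormalizer:
    """Per-channel, per-band min/max learned on a training set."""

    mins: np.ndarray  # B x C
    maxs: np.ndarray  # B x C
    bands: tuple[BandSpec, ...] = field(default_factory=tuple)


def band_reconstruct(x: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Keep real-FFT bins with frequency in [f_lo, f_hi); zero the rest.

    An exact orthogonal projection: idempotent, identity on pass-band
    sinusoids that sit on FFT bins, null on stop-band ones.  Works on a
    1-D signal or on a channels x samples array (last axis is time).
    """
    x = np.asarray(x, dtype=np.float64)
    if band.f_lo >= fs / 2:
        raise ValueError(f"band {band.name} lies entirely above Nyquist ({fs / 2} Hz)")
    tau = x.shape[-1]
    freqs = np.fft.rfftfreq(tau, d=1.0 / fs)
    keep = (freqs >= band.f_lo) & (freqs < band.f_hi)
    if not np.any(keep):
        raise ValueError(f"band {band.name} contains no resolvable FFT bin")
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=tau, axis=-1)


def gaussian_kernel(d2: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """exp(-d2 / (2 sigma^2)) for squared distance(s) d2 >= 0."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = np.asarray(d2, dtype=np.float64)
    if np.any(d2 < 0):
        raise ValueError("squared distances must be nonnegative")
    out = np.exp(-d2 / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def gfc_matrix(
    Xb: np.ndarray,
    sigma: float | str = "auto",
    eps_sigma: float = 1e-6,
    band: BandSpec | None = None,
) -> GFCMatrix:
    """Gaussian-kernel similarity matrix between the rows of ``Xb``.

    ``sigma="auto"`` uses the median of the C(C-1)/2 distinct pairwise
    Euclidean distances (self-distances excluded).  An all-identical
    trial (median distance 0) falls back to ``eps_sigma`` with a warning.
    """
    Xb = np.asarray(Xb, dtype=np.float64)
    if Xb.ndim != 2 or Xb.shape[0] < 2:
        raise ValueError("Xb must be C x tau with C >= 2")
    dists = pdist(Xb, metric="euclidean")
    if sigma == "auto":
        sig = float(np.median(dists))
        if sig == 0.0:
            warnings.warn("all channels identical; falling back to sigma=eps")
            sig = eps_sigma
    else:
        sig = float(sigma)
        if sig <= 0:
            raise ValueError("sigma must be positive")
    K = np.exp(-squareform(dists) ** 2 / (2.0 * sig**2))
    np.fill_diagonal(K, 1.0)
    if band is None:
        band = BandSpec("custom", 1.0, 2.0)
    return GFCMatrix(K=K, band=band, sigma=sig)


def flow_vector(K: GFCMatrix) -> FlowVector:
    """Per-channel mean coupling: g_c = (1/C) sum_{c' != c} K[c, c'].

    The divisor is C (not C-1), so values lie in [0, (C-1)/C]; the
    subsequent min-max normalization removes this fixed offset.
    """
    mat = K.K
    c = mat.shape[0]
    g = (mat.sum(axis=1) - np.diag(mat)) / c
    return FlowVector(g=g, band=K.band)


def trial_flows(
    trial: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    sigma: float | str = "auto",
) -> np.ndarray:
    """B x C flow matrix for one channels x samples trial."""
    out = np.empty((len(bands), trial.shape[0]))
    for b, band in enumerate(bands):
        xb = band_reconstruct(trial, band, fs)
        out[b] = flow_vector(gfc_matrix(xb, sigma=sigma, band=band)).g
    return out


def trialset_flows(
    trials: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    sigma: float | str = "auto",
) -> np.ndarray:
    """n x B x C flow tensor for a stack of trials."""
    return np.stack([trial_flows(t, fs, bands, sigma) for t in trials])


def fit_minmax(
    train_flows: np.ndarray,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
) -> MinMaxNormalizer:
    """Fit per-channel, per-band min/max on an n x B x C training tensor."""
    train_flows = np.asarray(train_flows, dtype=np.float64)
    if train_flows.ndim != 3 or train_flows.shape[0] < 2:
        raise ValueError("need an n x B x C tensor with n >= 2 training trials")
    return MinMaxNormalizer(
        mins=train_flows.min(axis=0),
        maxs=train_flows.max(axis=0),
        bands=tuple(bands),
    )


def apply_minmax(norm: MinMaxNormalizer, flows: np.ndarray) -> np.ndarray:
    """(g - min) / (max - min), clamped to [0, 1]; degenerate channels -> 0.5.

    Accepts a B x C matrix or an n x B x C tensor.
    """
    flows = np.asarray(flows, dtype=np.float64)
    single = flows.ndim == 2
    if single:
        flows = flows[None]
    if flows.shape[1:] != norm.mins.shape:
        raise ValueError(
            f"flow shape {flows.shape[1:]} does not match normalizer {norm.mins.shape}"
        )
    span = norm.maxs - norm.mins
    degenerate = span == 0
    safe_span = np.where(degenerate, 1.0, span)
    out = np.clip((flows - norm.mins) / safe_span, 0.0, 1.0)
    out[:, degenerate] = 0.5
    return out[0] if single else out
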