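"""Signal standardization, spherical-spline surface Laplacian, segmentation.

Standardization: common-average reference (each sample's channel mean
subtracted), zero-phase Butterworth band-pass, polyphase resampling.

The surface Laplacian (current-source-density transform) follows the
classical spherical-spline construction: electrode positions on a unit
sphere, spline weighting matrices built from a truncated Legendre series
over the cosine similarity between electrodes,

    g(cos) = (1/4pi) * sum_{n=1..Nmax} (2n+1) P_n(cos) / (n(n+1))^rho
    h(cos) = (1/4pi) * sum_{n=1..Nmax} (2n+1) P_n(cos) / (n(n+1))^(rho-1)

with stiffness ``rho`` (default 4) and a ridge ``lam`` on G.  Per time
sample the spline coefficients are obtained from the regularized system
with the mean-coefficient constraint, then mapped through H.  This acts
as a spatial high-pass that suppresses volume-conducted, spatially
constant components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.special import eval_legendre

from .data_io import Montage, Recording

__all__ = [
    "SplineMatrices",
    "standardize",
    "average_reference",
    "spline_matrices",
    "surface_laplacian",
    "segment",
]


def average_reference(rec: Recording) -> Recording:
    """Subtract each sample's across-channel mean (common average reference)."""
    sig = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return Recording(sig, rec.fs, list(rec.channel_labels))


def standardize(
    rec: Recording,
    lo: float = 4.0,
    hi: float = 40.0,
    order: int = 5,
    fs_out: float | None = 128.0,
) -> Recording:
    """Average-reference, zero-phase Butterworth band-pass, resample.

    The band-pass is applied forward-backward (zero phase) with
    second-order sections; resampling is polyphase FIR with a Kaiser
    window.  ``fs_out=None`` skips resampling.
    """
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError(f"band ({lo}, {hi}) not inside (0, Nyquist={rec.fs / 2})")
    fs_final = rec.fs if fs_out is None else float(fs_out)
    if hi >= fs_final / 2:
        raise ValueError(f"band edge {hi} Hz at or above output Nyquist {fs_final / 2} Hz")

    sig = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    sig = sps.sosfiltfilt(sos, sig, axis=1)
    if fs_out is not None and fs_out != rec.fs:
        from fractions import Fraction

        frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
        sig = sps.resample_poly(sig, frac.numerator, frac.denominator, axis=1)
    return Recording(sig, fs_final, list(rec.channel_labels))


@dataclass
class SplineMatrices:
    """Spherical-spline weighting matrices for one montage."""

    G: np.ndarray
    H: np.ndarray
    Gs: np.ndarray  # G + lam * I
    rho: int
    Nmax: int
    lam: float


def cosine_similarity_matrix(xyz: np.ndarray) -> np.ndarray:
    """cos(angle) between unit-sphere electrodes: 1 - |e - e'|^2 / 2."""
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    return np.clip(1.0 - d2 / 2.0, -1.0, 1.0)


def legendre_series(cosang: np.ndarray, exponent: float, Nmax: int) -> np.ndarray:
    """(1/4pi) * sum_{n=1..Nmax} (2n+1) P_n(cosang) / (n(n+1))^exponent.

    Evaluated with the three-term Legendre recurrence, vectorized over
    the input array.
    """
    x = np.asarray(cosang, dtype=np.float64)
    p_prev = np.ones_like(x)   # P_0
    p_curr = x.copy()          # P_1
    acc = np.zeros_like(x)
    for n in range(1, Nmax + 1):
        coeff = (2 * n + 1) / (n * (n + 1)) ** exponent
        acc += coeff * p_curr
        # recurrence: (n+1) P_{n+1} = (2n+1) x P_n - n P_{n-1}
        p_next = ((2 * n + 1) * x * p_curr - n * p_prev) / (n + 1)
        p_prev, p_curr = p_curr, p_next
    return acc / (4.0 * np.pi)


def legendre_series_oracle(cosang: np.ndarray, exponent: float, Nmax: int) -> np.ndarray:
    """Same series via scipy's explicit Legendre polynomials (cross-check)."""
    x = np.asarray(cosang, dtype=np.float64)
    acc = np.zeros_like(x)
    for n in range(1, Nmax + 1):
        acc += (2 * n + 1) / (n * (n + 1)) ** exponent * eval_legendre(n, x)
    return acc / (4.0 * np.pi)


def spline_matrices(
    m: Montage,
    rho: int = 4,
    Nmax: int = 50,
    lam: float = 1e-5,
) -> SplineMatrices:
    """Build the spherical-spline G and H matrices for a montage."""
    if m.n_channels < 4:
        raise ValueError("need at least 4 electrodes for the spherical spline")
    cosang = cosine_similarity_matrix(m.xyz)
    off_diag = cosang[~np.eye(m.n_channels, dtype=bool)]
    if np.any(off_diag >= 1.0 - 1e-12):
        raise ValueError("coincident electrodes in montage (cosine similarity 1)")
    G = legendre_series(cosang, rho, Nmax)
    H = legendre_series(cosang, rho - 1, Nmax)
    Gs = G + lam * np.eye(m.n_channels)
    return SplineMatrices(G=G, H=H, Gs=Gs, rho=rho, Nmax=Nmax, lam=lam)


def _laplacian_operator(sm: SplineMatrices) -> np.ndarray:
    """Linear map L with XL = H @ L @ X (spline solve + mean constraint)."""
    c = sm.Gs.shape[0]
    try:
        g_inv = np.linalg.inv(sm.Gs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Gs is numerically singular; increase lam") from exc
    cond = np.linalg.cond(sm.Gs)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"Gs ill-conditioned (cond={cond:.3e}); increase lam")
    ones = np.ones((c, 1))
    denom = float((ones.T @ g_inv @ ones).item())
    # coefficients: c = Ginv (x - c0 * 1), c0 = (1^T Ginv x) / (1^T Ginv 1)
    return g_inv - (g_inv @ ones @ ones.T @ g_inv) / denom


def surface_laplacian(rec: Recording, sm: SplineMatrices) -> Recording:
    """Apply the spherical-spline surface Laplacian to every time sample."""
    if rec.n_channels != sm.Gs.shape[0]:
        raise ValueError("recording channel count does not match spline matrices")
    op = _laplacian_operator(sm)
    out = sm.H @ (op @ rec.signal)
    return Recording(out, rec.fs, list(rec.channel_labels))


def surface_laplacian_oracle(rec: Recording, sm: SplineMatrices) -> Recording:
    """Per-sample dense-solve reference implementation (slow; for checks)."""
    c = rec.n_channels
    ones = np.ones(c)
    g_inv = np.linalg.inv(sm.Gs)
    out = np.empty_like(rec.signal)
    for t in range(rec.n_samples):
        x = rec.signal[:, t]
        c0 = (ones @ g_inv @ x) / (ones @ g_inv @ ones)
        coeffs = g_inv @ (x - c0 * ones)
        out[:, t] = sm.H @ coeffs
    return Recording(out, rec.fs, list(rec.channel_labels))


def segment(rec: Recording, ts: float, te: float) -> Recording:
    """Keep samples in the half-open window [round(ts*fs), round(te*fs))."""
    if not 0 <= ts < te <= rec.n_samples / rec.fs + 1e-12:
        raise ValueError(f"window [{ts}, {te}) s outside record of {rec.duration:.3f} s")
    i0 = int(round(ts * rec.fs))
    i1 = int(round(te * rec.fs))
    if i1 <= i0:
        raise ValueError("empty segmentation window")
    return Recording(rec.signal[:, i0:i1], rec.fs, list(rec.channel_labels))
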