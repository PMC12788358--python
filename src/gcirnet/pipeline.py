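"""End-to-end estimator: trials -> Laplacian -> GFC flows -> images -> VAE.

Two stages with different leakage properties are kept separate:

* Per-trial, training-independent transforms (surface Laplacian, window
  segmentation, band-limited GFC flow extraction) are computed once per
  trial set with :func:`preprocess_trialset` / :func:`compute_flows`.
* Training-dependent state (channel-wise min-max normalizer, the mean
  image of the reconstruction loss, the network weights) lives in
  :class:`FlowImageClassifier`, which is refit per cross-validation
  split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import (
    DEFAULT_BANDS,
    BandSpec,
    MinMaxNormalizer,
    apply_minmax,
    fit_minmax,
    trialset_flows,
)
from .data_io import Montage, TrialSet
from .model import (
    ArchitectureConfig,
    GCIRNet,
    LossWeights,
    TrainConfig,
    build_model,
    predict,
    train,
)
from .preprocess import segment, spline_matrices, surface_laplacian, standardize
from .topomap import PixelGrid, flows_to_images

__all__ = ["preprocess_trialset", "compute_flows", "FlowImageClassifier"]


def preprocess_trialset(
    ts: TrialSet,
    montage: Montage,
    window: tuple[float, float] | None = None,
    band: tuple[float, float] | None = None,
    order: int = 5,
    fs_out: float | None = None,
    laplacian: bool = True,
    rho: int = 4,
    Nmax: int = 50,
    lam: float = 1e-5,
) -> TrialSet:
    """Apply optional standardization, the surface Laplacian and windowing.

    ``band`` enables the average-reference + Butterworth + resampling
    front end (for raw imports); synthetic or pre-filtered trials can
    skip it.  Channel order must match the montage.
    """
    if list(ts.channel_labels) != list(montage.labels):
        raise ValueError("trial channel order does not match montage")
    sm = spline_matrices(montage, rho=rho, Nmax=Nmax, lam=lam) if laplacian else None
    out = []
    fs = ts.fs
    for i in range(ts.n_trials):
        rec = ts.recording(i)
        if band is not None:
            rec = standardize(rec, band[0], band[1], order=order, fs_out=fs_out)
        if sm is not None:
            rec = surface_laplacian(rec, sm)
        if window is not None:
            rec = segment(rec, window[0], window[1])
        out.append(rec.signal)
        fs = rec.fs
    return TrialSet(np.stack(out), ts.labels, fs, list(ts.channel_labels), dict(ts.metadata))


def compute_flows(
    ts: TrialSet,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    sigma: float | str = "auto",
) -> np.ndarray:
    """n x B x C raw (unnormalized) GFC flow tensor for a trial set."""
    return trialset_flows(ts.trials, ts.fs, bands=bands, sigma=sigma)


@dataclass
class FlowImageClassifier:
    """Min-max normalization + topographic rendering + VAE classifier.

    A scikit-learn-style estimator over precomputed flow tensors:
    ``fit(flows, labels)`` learns the channel-wise normalizer on the
    training flows, renders the band images, holds out a stratified
    fraction for early stopping, and trains the network; ``predict``
    renders unseen flows with the frozen normalizer and classifies at
    the posterior mean.
    """

    xy: np.ndarray
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    image_size: int = 40
    weights: LossWeights = field(default_factory=lambda: LossWeights(0.25, 0.5, 0.25))
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    latent_dim: int = 128
    val_fraction: float = 0.15
    seed: int = 0

    normalizer: MinMaxNormalizer | None = None
    model: GCIRNet | None = None
    grid: PixelGrid | None = None
    Ybar: np.ndarray | None = None

    def _render(self, flows: np.ndarray) -> np.ndarray:
        assert self.normalizer is not None
        norm = apply_minmax(self.normalizer, flows)
        images, _, grid = flows_to_images(
            norm, self.xy, self.bands, H=self.image_size, W=self.image_size, grid=self.grid
        )
        self.grid = grid
        return images

    def fit(self, flows: np.ndarray, labels: np.ndarray) -> "FlowImageClassifier":
        flows = np.asarray(flows, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.float64)
        self.normalizer = fit_minmax(flows, self.bands)
        self.grid = PixelGrid.from_points(self.xy, self.image_size, self.image_size)
        images = self._render(flows)

        # stratified validation split for early stopping
        rng = np.random.default_rng(self.seed)
        cls = np.argmax(labels, axis=1)
        val_idx: list[int] = []
        for c in np.unique(cls):
            members = np.flatnonzero(cls == c)
            k = max(1, int(round(self.val_fraction * members.size)))
            val_idx.extend(rng.permutation(members)[:k])
        val_mask = np.zeros(len(cls), dtype=bool)
        val_mask[val_idx] = True

        arch = ArchitectureConfig(
            input_shape=images.shape[1:],
            latent_dim=self.latent_dim,
            n_classes=labels.shape[1],
        )
        self.model = build_model(arch, self.seed)
        self.Ybar = images[~val_mask].mean(axis=0)
        train(
            self.model,
            images[~val_mask], labels[~val_mask],
            images[val_mask], labels[val_mask],
            self.weights,
            cfg=self.train_cfg,
            seed=self.seed,
            Ybar=self.Ybar,
        )
        return self

    def predict_proba(self, flows: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("estimator is not fitted")
        images = self._render(np.asarray(flows, dtype=np.float64))
        return predict(self.model, images)["probs"]

    def predict(self, flows: np.ndarray) -> np.ndarray:
        """Predicted class indices."""
        return np.argmax(self.predict_proba(flows), axis=1)
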