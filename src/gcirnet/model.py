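"""Connectivity-image VAE: architecture, normalized losses, training.

The network is a LeNet-style variational autoencoder over the stacked
band topographic maps.  The encoder is three 3x3 convolutions (6, 16,
120 filters, SELU) with 2x2 average pooling after the first two, a
dense bottleneck, and two linear heads for the posterior mean and
log-variance of a 128-D latent Gaussian.  The decoder mirrors it with
dense layers, nearest-neighbor upsampling and 3x3 (transposed, stride-1,
hence plain) convolutions down to a sigmoid reconstruction; a small MLP
classifier reads the same latent vector.

Training minimizes a convex combination on the simplex

    L = w_rec * NMSE + w_cla * NBCE + w_reg * NKL

where each term is normalized so that a non-informative predictor
scores 1: reconstruction error is divided by the batch deviation from
the training mean image, cross-entropy by the cross-entropy of the
uniform prediction, and the KL term by N log N.  This keeps the three
objectives on a comparable scale so the simplex weights are meaningful.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import h5py
import numpy as np

from .nn import (
    SELU,
    Adam,
    AvgPool2x2,
    Conv2D,
    Dense,
    Flatten,
    Layer,
    Reshape,
    Sequential,
    Sigmoid,
    Upsample2x2,
    softmax,
)

__all__ = [
    "ArchitectureConfig",
    "LatentStats",
    "LossWeights",
    "TrainConfig",
    "GCIRNet",
    "build_model",
    "reparameterize",
    "loss_rec",
    "loss_cla",
    "loss_reg",
    "total_loss",
    "train",
    "search_loss_weights",
    "simplex_lattice",
    "predict",
    "save_model",
    "load_model",
]

_CLA_EPS = 1e-7
_LOGVAR_CLIP = 30.0


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shapes and sizes of the encoder/decoder/classifier stack."""

    input_shape: tuple[int, int, int] = (40, 40, 4)
    conv_filters: tuple[int, int, int] = (6, 16, 120)
    latent_dim: int = 128
    classifier_hidden: int = 128
    n_classes: int = 2

    def __post_init__(self) -> None:
        h, w, _ = self.input_shape
        if h % 4 or w % 4:
            raise ValueError("input height/width must be divisible by 4")
        if self.latent_dim < 1:
            raise ValueError("latent dim must be >= 1")

    @property
    def flat_features(self) -> int:
        h, w, _ = self.input_shape
        return (h // 4) * (w // 4) * self.conv_filters[2]


@dataclass
class LatentStats:
    mu: np.ndarray
    logvar: np.ndarray


@dataclass(frozen=True)
class LossWeights:
    """Convex weights for reconstruction / classification / regularization."""

    lam_rec: float
    lam_cla: float
    lam_reg: float

    def __post_init__(self) -> None:
        if min(self.lam_rec, self.lam_cla, self.lam_reg) < 0:
            raise ValueError("loss weights must be nonnegative")
        if abs(self.lam_rec + self.lam_cla + self.lam_reg - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to one")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam_rec, self.lam_cla, self.lam_reg])


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    patience: int = 10


class GCIRNet:
    """Encoder/decoder/classifier with shared 128-D Gaussian latent."""

    def __init__(self, cfg: ArchitectureConfig, seed: int) -> None:
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        h, w, b = cfg.input_shape
        f1, f2, f3 = cfg.conv_filters
        flat = cfg.flat_features

        self.encoder = Sequential([
            Conv2D(b, f1, rng), SELU(),
            AvgPool2x2(),
            Conv2D(f1, f2, rng), SELU(),
            AvgPool2x2(),
            Conv2D(f2, f3, rng), SELU(),
            Flatten(),
            Dense(flat, cfg.latent_dim, rng), SELU(),
        ])
        self.dense_mu = Dense(cfg.latent_dim, cfg.latent_dim, rng)
        self.dense_logvar = Dense(cfg.latent_dim, cfg.latent_dim, rng)
        self.decoder = Sequential([
            Dense(cfg.latent_dim, cfg.latent_dim, rng), SELU(),
            Dense(cfg.latent_dim, flat, rng), SELU(),
            Reshape((h // 4, w // 4, f3)),
            Conv2D(f3, f2, rng), SELU(),
            Upsample2x2(),
            Conv2D(f2, f1, rng), SELU(),
            Upsample2x2(),
            Conv2D(f1, b, rng), Sigmoid(),
        ])
        self.classifier = Sequential([
            Dense(cfg.latent_dim, cfg.classifier_hidden, rng), SELU(),
            Dense(cfg.classifier_hidden, cfg.n_classes, rng),
        ])
        self.history: dict[str, list[float]] = {}

    # named encoder conv layers for relevance analysis
    _CONV_INDEX = {"conv1": 0, "conv2": 3, "conv3": 6}

    @property
    def modules(self) -> list[Sequential]:
        return [self.encoder, self.decoder, self.classifier]

    @property
    def params(self) -> list[np.ndarray]:
        return (
            self.encoder.params
            + self.dense_mu.params
            + self.dense_logvar.params
            + self.decoder.params
            + self.classifier.params
        )

    @property
    def grads(self) -> list[np.ndarray]:
        return (
            self.encoder.grads
            + self.dense_mu.grads
            + self.dense_logvar.grads
            + self.decoder.grads
            + self.classifier.grads
        )

    def zero_grad(self) -> None:
        self.encoder.zero_grad()
        self.dense_mu.zero_grad()
        self.dense_logvar.zero_grad()
        self.decoder.zero_grad()
        self.classifier.zero_grad()

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    def encoder_shapes(self, n: int = 1) -> list[tuple[int, ...]]:
        """Output shape of every encoder layer for a batch of size n."""
        x = np.zeros((n,) + self.cfg.input_shape)
        shapes = []
        for layer in self.encoder.layers:
            x = layer.forward(x)
            shapes.append(x.shape[1:])
        return shapes

    # ---- forward passes -------------------------------------------------

    def encode(self, Y: np.ndarray) -> LatentStats:
        hE = self.encoder.forward(Y)
        mu = self.dense_mu.forward(hE)
        logvar = np.clip(self.dense_logvar.forward(hE), -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return LatentStats(mu=mu, logvar=logvar)

    def forward(
        self, Y: np.ndarray, eps: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, LatentStats, np.ndarray]:
        """Full pass: returns (reconstruction, probabilities, stats, z).

        With ``eps=None`` the latent is the posterior mean (deterministic
        inference); otherwise z = mu + exp(logvar/2) * eps.
        """
        ls = self.encode(Y)
        z = ls.mu if eps is None else reparameterize(ls, eps)
        Yhat = self.decoder.forward(z)
        logits = self.classifier.forward(z)
        return Yhat, softmax(logits), ls, z


def build_model(cfg: ArchitectureConfig, seed: int) -> GCIRNet:
    """Construct a network with deterministic Glorot init under ``seed``."""
    return GCIRNet(cfg, seed)


def reparameterize(ls: LatentStats, eps: np.ndarray) -> np.ndarray:
    """z = mu + exp(logvar / 2) * eps."""
    logvar = np.clip(ls.logvar, -_LOGVAR_CLIP, _LOGVAR_CLIP)
    return ls.mu + np.exp(0.5 * logvar) * eps


# ---- normalized loss terms ---------------------------------------------


def loss_rec(Y: np.ndarray, Yhat: np.ndarray, Ybar: np.ndarray) -> float:
    """Normalized MSE: sum_i |Y_i - Yhat_i|_F^2 / sum_i |Y_i - Ybar|_F^2.

    ``Ybar`` is the training-set mean image, frozen at fit time.
    """
    num = float(np.sum((Y - Yhat) ** 2))
    den = float(np.sum((Y - Ybar) ** 2))
    if den == 0.0:
        raise ValueError("all images equal the mean image; NMSE undefined")
    return num / den


def loss_cla(P: np.ndarray, Phat: np.ndarray) -> float:
    """Normalized cross-entropy: mean_i CE(p_i, phat_i) / CE(u, phat_i).

    ``u`` is the uniform label (1/Q, ..., 1/Q); predictions are clipped
    to [eps, 1 - eps] inside both numerator and denominator, so a
    uniform predictor scores exactly 1.
    """
    P = np.asarray(P, dtype=np.float64)
    Phat = np.asarray(Phat, dtype=np.float64)
    if not np.allclose(Phat.sum(axis=1), 1.0, atol=1e-6) or np.any(Phat < -1e-12):
        raise ValueError("predicted rows must lie on the probability simplex")
    q = P.shape[1]
    logp = np.log(np.clip(Phat, _CLA_EPS, 1.0 - _CLA_EPS))
    ce = -(P * logp).sum(axis=1)
    ce_u = -logp.sum(axis=1) / q
    return float(np.mean(ce / ce_u))


def loss_reg(ls: LatentStats) -> float:
    """Normalized KL to the unit Gaussian prior: (1/(N ln N)) sum_i KL_i.

    KL_i has the closed form 0.5 * sum_d (mu^2 + sigma^2 - 1 - log sigma^2).
    For N = 1 the ln N normalizer degenerates; it is guarded by
    max(ln N, 1) with a warning.
    """
    mu, logvar = ls.mu, np.clip(ls.logvar, -_LOGVAR_CLIP, _LOGVAR_CLIP)
    n = mu.shape[0]
    kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar)
    if n == 1:
        warnings.warn("single-sample batch: ln N normalizer guarded to 1")
    norm = max(np.log(n), 1.0) if n == 1 else n * np.log(n)
    return float(kl / norm)


def total_loss(w: LossWeights, rec: float, cla: float, reg: float) -> float:
    return w.lam_rec * rec + w.lam_cla * cla + w.lam_reg * reg


# ---- loss gradients (at the network outputs) ----------------------------


def _loss_and_output_grads(
    Y: np.ndarray,
    Yhat: np.ndarray,
    Ybar: np.ndarray,
    P: np.ndarray,
    Phat: np.ndarray,
    ls: LatentStats,
    w: LossWeights,
) -> tuple[dict[str, float], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Loss components plus gradients w.r.t. Yhat, logits, mu, logvar.

    The mu/logvar gradients returned here cover only the explicit KL
    term; gradients flowing through z are added by the caller.
    """
    n = Y.shape[0]
    q = P.shape[1]

    rec = loss_rec(Y, Yhat, Ybar)
    den = float(np.sum((Y - Ybar) ** 2))
    dYhat = w.lam_rec * (-2.0 * (Y - Yhat) / den)

    # classification: d(NBCE)/d(logits) via per-sample softmax Jacobian
    clipped = np.clip(Phat, _CLA_EPS, 1.0 - _CLA_EPS)
    active = (Phat > _CLA_EPS) & (Phat < 1.0 - _CLA_EPS)
    logp = np.log(clipped)
    ce = -(P * logp).sum(axis=1)
    ce_u = -logp.sum(axis=1) / q
    cla = float(np.mean(ce / ce_u))
    # d ratio / d phat, zero where the clip is active
    dphat = (-P / clipped * ce_u[:, None] + ce[:, None] * (1.0 / q) / clipped) / (
        ce_u[:, None] ** 2
    )
    dphat = np.where(active, dphat, 0.0) / n
    # softmax Jacobian: dL/da = phat * (dphat - sum_j dphat_j phat_j)
    inner = (dphat * Phat).sum(axis=1, keepdims=True)
    dlogits = w.lam_cla * Phat * (dphat - inner)

    mu, logvar = ls.mu, ls.logvar
    kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar)
    norm = max(np.log(n), 1.0) if n == 1 else n * np.log(n)
    reg = float(kl / norm)
    dmu_kl = w.lam_reg * mu / norm
    dlogvar_kl = w.lam_reg * 0.5 * (np.exp(logvar) - 1.0) / norm

    losses = {"rec": rec, "cla": cla, "reg": reg,
              "total": total_loss(w, rec, cla, reg)}
    return losses, dYhat, dlogits, dmu_kl, dlogvar_kl


def _train_step(
    model: GCIRNet,
    Y: np.ndarray,
    P: np.ndarray,
    Ybar: np.ndarray,
    w: LossWeights,
    eps: np.ndarray,
) -> dict[str, float]:
    """One forward/backward pass; leaves gradients accumulated in model."""
    model.zero_grad()
    hE = model.encoder.forward(Y)
    mu = model.dense_mu.forward(hE)
    logvar = np.clip(model.dense_logvar.forward(hE), -_LOGVAR_CLIP, _LOGVAR_CLIP)
    ls = LatentStats(mu=mu, logvar=logvar)
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    Yhat = model.decoder.forward(z)
    logits = model.classifier.forward(z)
    Phat = softmax(logits)

    losses, dYhat, dlogits, dmu, dlogvar = _loss_and_output_grads(
        Y, Yhat, Ybar, P, Phat, ls, w
    )
    dz = model.decoder.backward(dYhat) + model.classifier.backward(dlogits)
    dmu = dmu + dz
    dlogvar = dlogvar + dz * eps * 0.5 * sigma
    dhE = model.dense_mu.backward(dmu) + model.dense_logvar.backward(dlogvar)
    model.encoder.backward(dhE)
    return losses


def _eval_losses(
    model: GCIRNet,
    Y: np.ndarray,
    P: np.ndarray,
    Ybar: np.ndarray,
    w: LossWeights,
) -> dict[str, float]:
    """Deterministic evaluation at the posterior mean (z = mu)."""
    Yhat, Phat, ls, _ = model.forward(Y)
    rec = loss_rec(Y, Yhat, Ybar)
    cla = loss_cla(P, Phat)
    reg = loss_reg(ls)
    return {"rec": rec, "cla": cla, "reg": reg, "total": total_loss(w, rec, cla, reg)}


def train(
    model: GCIRNet,
    Y_train: np.ndarray,
    P_train: np.ndarray,
    Y_val: np.ndarray,
    P_val: np.ndarray,
    w: LossWeights,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    Ybar: np.ndarray | None = None,
) -> GCIRNet:
    """Adam training with early stopping on validation total loss.

    Shuffling and the reparameterization draws come from one generator
    seeded with ``seed``; the best-validation parameters are restored on
    exit.  ``Ybar`` defaults to the training-set mean image and is
    frozen for validation.  Per-epoch loss components are recorded in
    ``model.history``.
    """
    if cfg is None:
        cfg = TrainConfig()
    if Y_train.shape[0] == 0 or Y_val.shape[0] == 0:
        raise ValueError("empty train or validation split")
    rng = np.random.default_rng(seed)
    if Ybar is None:
        Ybar = Y_train.mean(axis=0)
    opt = Adam(model.params, lr=cfg.lr)
    history: dict[str, list[float]] = {
        k: [] for k in ("rec", "cla", "reg", "total", "val_rec", "val_cla", "val_reg", "val_total")
    }
    best_val = np.inf
    best_state = model.get_state()
    best_epoch = -1
    n = Y_train.shape[0]
    latent = model.cfg.latent_dim
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = {"rec": 0.0, "cla": 0.0, "reg": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            eps = rng.standard_normal((idx.size, latent))
            losses = _train_step(model, Y_train[idx], P_train[idx], Ybar, w, eps)
            opt.step(model.grads)
            for k in sums:
                sums[k] += losses[k]
            n_batches += 1
        for k in sums:
            history[k].append(sums[k] / n_batches)
        val = _eval_losses(model, Y_val, P_val, Ybar, w)
        for k in ("rec", "cla", "reg", "total"):
            history[f"val_{k}"].append(val[k])
        if val["total"] < best_val - 1e-12:
            best_val = val["total"]
            best_state = model.get_state()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    model.set_state(best_state)
    model.history = history
    model.history["best_epoch"] = [float(best_epoch)]
    return model


def simplex_lattice(step: float = 0.1) -> list[LossWeights]:
    """Lattice of simplex weight triples with the given step (plus vertices)."""
    k = int(round(1.0 / step))
    out = []
    for i, j in product(range(k + 1), repeat=2):
        if i + j <= k:
            rec, cla = i / k, j / k
            out.append(LossWeights(rec, cla, round(1.0 - rec - cla, 12)))
    return out


def search_loss_weights(
    Y_train: np.ndarray,
    P_train: np.ndarray,
    Y_val: np.ndarray,
    P_val: np.ndarray,
    arch: ArchitectureConfig,
    candidates: Sequence[LossWeights] | None = None,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> LossWeights:
    """Pick the simplex weights minimizing validation total loss.

    Each candidate trains a freshly initialized model (same seed, so
    initializations are identical across candidates) for the short run
    described by ``cfg``; ties break toward the earlier candidate.
    """
    if candidates is None:
        candidates = simplex_lattice(0.1)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    if len(candidates) == 1:
        return candidates[0]
    if cfg is None:
        cfg = TrainConfig(epochs=20, patience=5)
    best_w, best_val = candidates[0], np.inf
    Ybar = Y_train.mean(axis=0)
    for w in candidates:
        model = build_model(arch, seed)
        train(model, Y_train, P_train, Y_val, P_val, w, cfg=cfg, seed=seed)
        score = _eval_losses(model, Y_val, P_val, Ybar, w)["total"]
        if score < best_val - 1e-12:
            best_val = score
            best_w = w
    return best_w


def predict(model: GCIRNet, images: np.ndarray) -> dict[str, np.ndarray]:
    """Deterministic inference at z = mu.

    Returns probabilities, latent stats, latent vectors and
    reconstructions for a batch of images.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.shape[1:] != model.cfg.input_shape:
        raise ValueError(
            f"image shape {images.shape[1:]} does not match model input {model.cfg.input_shape}"
        )
    Yhat, Phat, ls, z = model.forward(images)
    return {
        "probs": Phat,
        "mu": ls.mu,
        "logvar": ls.logvar,
        "z": z,
        "reconstruction": Yhat,
    }


def save_model(model: GCIRNet, path: str) -> None:
    """Checkpoint: HDF5 parameter tree plus JSON-encoded config."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(
            {
                "input_shape": list(model.cfg.input_shape),
                "conv_filters": list(model.cfg.conv_filters),
                "latent_dim": model.cfg.latent_dim,
                "classifier_hidden": model.cfg.classifier_hidden,
                "n_classes": model.cfg.n_classes,
                "seed": model.seed,
            }
        )
        for i, p in enumerate(model.params):
            f.create_dataset(f"param_{i:04d}", data=p)


def load_model(path: str) -> GCIRNet:
    with h5py.File(path, "r") as f:
        cfg_d = json.loads(f.attrs["config"])
        model = build_model(
            ArchitectureConfig(
                input_shape=tuple(cfg_d["input_shape"]),
                conv_filters=tuple(cfg_d["conv_filters"]),
                latent_dim=cfg_d["latent_dim"],
                classifier_hidden=cfg_d["classifier_hidden"],
                n_classes=cfg_d["n_classes"],
            ),
            seed=cfg_d["seed"],
        )
        state = [f[f"param_{i:04d}"][()] for i in range(len(model.params))]
    model.set_state(state)
    return model
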