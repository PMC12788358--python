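"""Interpretability: Grad-CAM++ relevance, electrode mapping, edge graphs.

Grad-CAM++ scores the spatial relevance of each encoder convolution for
one class: with first-order gradients g = d(logit_c)/dA of the class
logit with respect to a layer's (post-activation) feature maps A, the
exponential-score form reduces the higher-order terms to powers of g,

    alpha = g^2 / (2 g^2 + sum_spatial(A g^3)),
    w_k   = sum_spatial(alpha_k * relu(g_k)),
    CAM   = relu(sum_k w_k A_k),

bilinearly upsampled to the input resolution and max-normalized.  CAM
values are bilinearly sampled at electrode pixel positions to obtain
per-channel relevance, and the strongest connectivity-matrix edges (by
percentile band) are exported as an undirected graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .connectivity import GFCMatrix
from .model import GCIRNet
from .nn import Conv2D
from .topomap import PixelGrid

__all__ = [
    "RelevanceMap",
    "EdgeGraph",
    "gradcam_pp",
    "cam_to_channels",
    "edge_percentile_graph",
    "extract_latent",
]

_EPS = 1e-8

CONV_LAYERS = ("conv1", "conv2", "conv3")


@dataclass
class RelevanceMap:
    cam: np.ndarray          # H x W in [0, 1]
    layer: str
    class_idx: int


@dataclass
class EdgeGraph:
    """Undirected weighted edges retained from a connectivity matrix."""

    edges: list[tuple[int, int, float]]
    lo_pct: float
    hi_pct: float
    lo_value: float
    hi_value: float


def _encoder_activation_index(model: GCIRNet, layer: str) -> int:
    """Index of the post-SELU activation of a named encoder convolution."""
    conv_positions = [
        i for i, lay in enumerate(model.encoder.layers) if isinstance(lay, Conv2D)
    ]
    names = {f"conv{k + 1}": pos for k, pos in enumerate(conv_positions)}
    if layer not in names:
        raise ValueError(f"unknown conv layer '{layer}'; choose from {sorted(names)}")
    return names[layer] + 1  # the SELU following the convolution


def _score_gradients(
    model: GCIRNet, image: np.ndarray, layer: str, class_idx: int
) -> tuple[np.ndarray, np.ndarray]:
    """(A, dS/dA) for one image: activations of the named layer and the
    gradient of the class logit (at z = mu) with respect to them."""
    act_idx = _encoder_activation_index(model, layer)
    x = image[None] if image.ndim == 3 else image
    if x.shape[0] != 1:
        raise ValueError("gradcam operates on a single image")
    outs = []
    h = x
    for lay in model.encoder.layers:
        h = lay.forward(h)
        outs.append(h)
    hE = h
    mu = model.dense_mu.forward(hE)
    logits = model.classifier.forward(mu)
    if not 0 <= class_idx < logits.shape[1]:
        raise ValueError(f"class index {class_idx} out of range")
    model.zero_grad()
    dlogits = np.zeros_like(logits)
    dlogits[0, class_idx] = 1.0
    dmu = model.classifier.backward(dlogits)
    dh = model.dense_mu.backward(dmu)
    for lay in reversed(model.encoder.layers[act_idx + 1 :]):
        dh = lay.backward(dh)
    model.zero_grad()
    return outs[act_idx][0], dh[0]


def gradcam_pp(
    model: GCIRNet, image: np.ndarray, layer: str, class_idx: int
) -> RelevanceMap:
    """Grad-CAM++ relevance of one encoder conv layer for one class.

    Returns a nonnegative map at input resolution, divided by its max
    (an all-zero map is returned as-is).
    """
    A, grad = _score_gradients(model, image, layer, class_idx)
    g2 = grad**2
    g3 = grad**3
    denom = 2.0 * g2 + np.sum(A * g3, axis=(0, 1), keepdims=True)
    alpha = np.where(np.abs(denom) > _EPS, g2 / np.where(np.abs(denom) > _EPS, denom, 1.0), 0.0)
    weights = np.sum(alpha * np.maximum(grad, 0.0), axis=(0, 1))
    cam = np.maximum(np.sum(A * weights, axis=-1), 0.0)
    H, W, _ = model.cfg.input_shape
    if cam.shape != (H, W):
        cam = ndimage.zoom(cam, (H / cam.shape[0], W / cam.shape[1]), order=1,
                           mode="nearest", grid_mode=True)
        cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return RelevanceMap(cam=cam, layer=layer, class_idx=class_idx)


def cam_to_channels(cam: RelevanceMap | np.ndarray, xy: np.ndarray, grid: PixelGrid) -> np.ndarray:
    """Bilinear CAM samples at electrode positions (same projection/grid
    as the topographic rendering).  Electrodes outside the grid map to 0
    with a warning."""
    arr = cam.cam if isinstance(cam, RelevanceMap) else np.asarray(cam, dtype=np.float64)
    pix = grid.to_pixel(np.asarray(xy, dtype=np.float64))
    cols, rows = pix[:, 0], pix[:, 1]
    outside = (cols < -0.5) | (cols > grid.W - 0.5) | (rows < -0.5) | (rows > grid.H - 0.5)
    if np.any(outside):
        warnings.warn(f"{int(outside.sum())} electrode(s) outside the pixel grid; relevance 0")
    vals = ndimage.map_coordinates(arr, [rows, cols], order=1, mode="nearest")
    vals[outside] = 0.0
    return np.clip(vals, 0.0, 1.0)


def edge_percentile_graph(
    K: GFCMatrix | np.ndarray, lo_pct: float = 95.0, hi_pct: float = 100.0
) -> EdgeGraph:
    """Retain the undirected edges whose weight falls in the given
    percentile band of the off-diagonal upper-triangle weights
    (linear-interpolated percentiles; ties at the bounds included)."""
    if lo_pct >= hi_pct:
        raise ValueError("lo percentile must be below hi percentile")
    mat = K.K if isinstance(K, GFCMatrix) else np.asarray(K, dtype=np.float64)
    c = mat.shape[0]
    iu, ju = np.triu_indices(c, k=1)
    w = mat[iu, ju]
    lo_val, hi_val = np.percentile(w, [lo_pct, hi_pct])
    keep = (w >= lo_val) & (w <= hi_val)
    edges = [(int(i), int(j), float(v)) for i, j, v in zip(iu[keep], ju[keep], w[keep])]
    return EdgeGraph(edges=edges, lo_pct=lo_pct, hi_pct=hi_pct,
                     lo_value=float(lo_val), hi_value=float(hi_val))


def extract_latent(model: GCIRNet, images: np.ndarray) -> np.ndarray:
    """Posterior-mean latent vectors (n x latent_dim) for a batch of images.

    The 2-D embedding of these vectors (e.g. t-SNE) is left to
    off-the-shelf tools.
    """
    from .model import predict

    return predict(model, np.asarray(images, dtype=np.float64))["mu"]
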