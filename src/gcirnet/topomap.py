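"""Topographic image rendering from per-electrode flow values.

Electrode positions on the unit sphere are flattened with an azimuthal
equidistant projection about the vertex (radius = polar angle, azimuth
preserved), then Delaunay-triangulated.  Each pixel center inside the
convex hull is filled by linear barycentric interpolation within its
enclosing triangle; pixels outside the hull are zero and excluded from
the validity mask.  Band images are stacked channel-last into the
H x W x B tensors consumed by the network (40 x 40 x 4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .connectivity import BandSpec, FlowVector

__all__ = [
    "PixelGrid",
    "TopoImage",
    "project_montage",
    "barycentric_value",
    "render_topomap",
    "stack_bands",
]

# barycentric coords may dip slightly negative on shared edges
_BARY_TOL = 1e-12


def project_montage(xyz: np.ndarray) -> np.ndarray:
    """Azimuthal equidistant projection about the vertex (+z direction).

    Each unit vector maps to polar coordinates (radius = polar angle
    from +z, azimuth preserved), then the set is rescaled to fit in
    [-1, 1]^2.  The vertex itself maps to the origin.
    """
    xyz = np.asarray(xyz, dtype=np.float64)
    norms = np.linalg.norm(xyz, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("electrode positions must be unit vectors")
    z = np.clip(xyz[:, 2], -1.0, 1.0)
    theta = np.arccos(z)  # polar angle in [0, pi]
    if np.any(theta > np.pi - 1e-9):
        raise ValueError("electrode at the antipode of the projection vertex")
    horiz = np.hypot(xyz[:, 0], xyz[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(horiz > 0, xyz[:, 0] / horiz, 0.0)
        uy = np.where(horiz > 0, xyz[:, 1] / horiz, 0.0)
    xy = np.stack([theta * ux, theta * uy], axis=1)
    scale = np.abs(xy).max()
    if scale > 0:
        xy = xy / scale
    return xy


def barycentric_value(p: np.ndarray, tri: np.ndarray, v: np.ndarray) -> float:
    """Linear interpolation of vertex values ``v`` at point ``p`` in ``tri``."""
    p = np.asarray(p, dtype=np.float64)
    tri = np.asarray(tri, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    t = np.column_stack([tri[1] - tri[0], tri[2] - tri[0]])
    det = np.linalg.det(t)
    if abs(det) < 1e-300:
        raise ValueError("degenerate (zero-area) triangle")
    lam12 = np.linalg.solve(t, p - tri[0])
    lam = np.array([1.0 - lam12.sum(), lam12[0], lam12[1]])
    if np.any(lam < -1e-9):
        raise ValueError("point lies outside the triangle")
    return float(lam @ v)


@dataclass(frozen=True)
class PixelGrid:
    """Uniform H x W lattice of pixel centers over padded electrode bounds."""

    H: int
    W: int
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @classmethod
    def from_points(cls, xy: np.ndarray, H: int, W: int, pad: float = 0.02) -> "PixelGrid":
        x_min, y_min = xy.min(axis=0)
        x_max, y_max = xy.max(axis=0)
        dx, dy = (x_max - x_min) * pad, (y_max - y_min) * pad
        return cls(H, W, x_min - dx, x_max + dx, y_min - dy, y_max + dy)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of pixel-cell centers; row 0 = y_min edge."""
        xs = self.x_min + (np.arange(self.W) + 0.5) * (self.x_max - self.x_min) / self.W
        ys = self.y_min + (np.arange(self.H) + 0.5) * (self.y_max - self.y_min) / self.H
        return xs, ys

    def to_pixel(self, xy: np.ndarray) -> np.ndarray:
        """Continuous pixel coordinates (col, row) of data-space points."""
        xy = np.asarray(xy, dtype=np.float64)
        col = (xy[..., 0] - self.x_min) / (self.x_max - self.x_min) * self.W - 0.5
        row = (xy[..., 1] - self.y_min) / (self.y_max - self.y_min) * self.H - 0.5
        return np.stack([col, row], axis=-1)


@dataclass
class TopoImage:
    """H x W x B stacked band maps in [0, 1] with an in-hull validity mask."""

    pixels: np.ndarray
    mask: np.ndarray
    bands: tuple[BandSpec, ...]
    grid: PixelGrid


def render_topomap(
    g: np.ndarray | FlowVector,
    xy: np.ndarray,
    H: int = 40,
    W: int = 40,
    grid: PixelGrid | None = None,
) -> tuple[np.ndarray, np.ndarray, PixelGrid]:
    """Render one flow vector to a single-band image.

    Returns ``(image, mask, grid)``: pixels inside the Delaunay hull are
    barycentric interpolations of the electrode values; outside pixels
    are 0 with ``mask`` false.
    """
    values = g.g if isinstance(g, FlowVector) else np.asarray(g, dtype=np.float64)
    xy = np.asarray(xy, dtype=np.float64)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 electrodes")
    if values.shape[0] != xy.shape[0]:
        raise ValueError("flow vector length does not match electrode count")
    try:
        tri = Delaunay(xy)
    except Exception as exc:  # qhull error on collinear input
        raise ValueError("electrode layout is degenerate (collinear?)") from exc
    if tri.nsimplex == 0:
        raise ValueError("electrode layout is degenerate (collinear?)")
    if grid is None:
        grid = PixelGrid.from_points(xy, H, W)
    xs, ys = grid.centers()
    gx, gy = np.meshgrid(xs, ys)  # shape H x W, row-major over y
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    simplex = tri.find_simplex(pts, tol=_BARY_TOL)
    inside = simplex >= 0
    img = np.zeros(pts.shape[0])
    if np.any(inside):
        s = simplex[inside]
        transform = tri.transform[s]
        bary12 = np.einsum(
            "nij,nj->ni", transform[:, :2, :], pts[inside] - transform[:, 2, :]
        )
        lam = np.column_stack([bary12, 1.0 - bary12.sum(axis=1)])
        lam = np.clip(lam, 0.0, 1.0)
        lam /= lam.sum(axis=1, keepdims=True)
        verts = tri.simplices[s]
        img[inside] = np.einsum("ni,ni->n", lam, values[verts])
    return img.reshape(grid.H, grid.W), inside.reshape(grid.H, grid.W), grid


def stack_bands(
    maps: list[np.ndarray],
    masks: list[np.ndarray],
    bands: tuple[BandSpec, ...],
    grid: PixelGrid,
    order: tuple[str, ...] | None = None,
) -> TopoImage:
    """Stack single-band images channel-last in canonical band order.

    ``order`` gives the canonical band-name sequence; if supplied, input
    maps (labelled by ``bands``) are reordered to match it.
    """
    if len(maps) != len(bands) or len(masks) != len(bands):
        raise ValueError("maps, masks and bands must align")
    for msk in masks[1:]:
        if msk.shape != masks[0].shape or not np.array_equal(msk, masks[0]):
            raise ValueError("band masks do not match")
    idx = list(range(len(bands)))
    if order is not None:
        names = [b.name for b in bands]
        if sorted(names) != sorted(order):
            raise ValueError("band names do not match requested order")
        idx = [names.index(name) for name in order]
    pixels = np.stack([maps[i] for i in idx], axis=-1)
    return TopoImage(
        pixels=pixels,
        mask=masks[0].copy(),
        bands=tuple(bands[i] for i in idx),
        grid=grid,
    )


def flows_to_images(
    flows_norm: np.ndarray,
    xy: np.ndarray,
    bands: tuple[BandSpec, ...],
    H: int = 40,
    W: int = 40,
    grid: PixelGrid | None = None,
) -> tuple[np.ndarray, np.ndarray, PixelGrid]:
    """Render an n x B x C normalized flow tensor to n x H x W x B images."""
    flows_norm = np.asarray(flows_norm, dtype=np.float64)
    n, B, _ = flows_norm.shape
    if grid is None:
        grid = PixelGrid.from_points(np.asarray(xy), H, W)
    images = np.empty((n, grid.H, grid.W, B))
    mask = None
    for i in range(n):
        for b in range(B):
            img, msk, _ = render_topomap(flows_norm[i, b], xy, grid=grid)
            images[i, :, :, b] = img
            mask = msk
    return images, mask, grid
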