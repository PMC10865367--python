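"""Closing a sparse set of contour pixels into a 1-pixel closed loop.

The pixel-averaging fusion algorithms emit an unordered, possibly sparse
cloud of boundary pixels. To connect them, the points are converted to polar
coordinates (theta, r) about a reference center and ordered by angle, which
turns the boundary into a single-valued radius function r(theta) — exact for
star-shaped contours, an approximation otherwise.

Two interpolation closers (every input pixel is preserved in the output):

* ``linear`` — consecutive polar-ordered points joined by straight chords,
  f(x) = ((x1 - x) y0 + (x - x0) y1) / (x1 - x0) on each segment.
* ``pchip`` — monotone (shape-preserving) piecewise-cubic Hermite
  interpolation of r as a periodic function of theta; no overshoot.

Two morphological active-contour closers (input pixels are *not* guaranteed
preserved): ``chan_vese`` and ``geodesic``, both initialized at the filled
convex hull of the points and evolved against an energy image built from the
point set's distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import PchipInterpolator
from skimage.filters import gaussian
from skimage.morphology import convex_hull_image, disk as disk_footprint
from skimage.segmentation import (
    morphological_chan_vese,
    morphological_geodesic_active_contour,
)

from .contour_ops import (
    ContourLine,
    fill_holes,
    internal_boundary,
    is_closed,
    thin_line,
)
from .errors import ConvergenceError, DegenerateGeometryError

CLOSING_METHODS = ("linear", "pchip", "chan_vese", "geodesic")

_THETA_QUANTUM = 1e-9  # rad; collisions within one quantum are merged


@dataclass(frozen=True)
class SparsePointSet:
    """Unordered contour pixels plus the polar reference center.

    ``center`` is a continuous (row, col) point; when omitted it defaults to
    the centroid of the points. ``shape`` is the output canvas; when omitted
    it is taken from the point bounding box plus a margin.
    """

    points: np.ndarray
    center: tuple[float, float] | None = None
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != 2:
            raise DegenerateGeometryError("points must be (K, 2) (row, col) pairs")
        pts = np.unique(pts, axis=0)
        if len(pts) < 3:
            raise DegenerateGeometryError(
                f"need >= 3 distinct points to close a contour, got {len(pts)}"
            )
        object.__setattr__(self, "points", pts)
        center = self.center
        if center is None:
            center = tuple(pts.mean(axis=0))
        center = (float(center[0]), float(center[1]))
        if not np.isfinite(center).all():
            raise DegenerateGeometryError("center must be finite")
        object.__setattr__(self, "center", center)
        if self.shape is None:
            h = int(pts[:, 0].max()) + 4
            w = int(pts[:, 1].max()) + 4
            object.__setattr__(self, "shape", (h, w))


@dataclass(frozen=True)
class PolarOrderedPoints:
    """(theta, r) samples sorted by strictly increasing angle."""

    theta: np.ndarray  # in [0, 2*pi)
    radius: np.ndarray
    center: tuple[float, float]


def to_polar(points: np.ndarray, center: tuple[float, float]):
    """Map (row, col) points to (theta, r) about ``center``.

    Angles are measured counterclockwise from the +col axis, with the row
    axis pointing down the image (so "up" in the image is theta = pi/2).
    """
    d_row = np.asarray(points, float)[:, 0] - center[0]
    d_col = np.asarray(points, float)[:, 1] - center[1]
    theta = np.mod(np.arctan2(-d_row, d_col), 2 * np.pi)
    radius = np.hypot(d_row, d_col)
    return theta, radius


def from_polar(theta, radius, center: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`to_polar`; returns continuous (row, col) points."""
    rows = center[0] - np.asarray(radius) * np.sin(theta)
    cols = center[1] + np.asarray(radius) * np.cos(theta)
    return np.column_stack([rows, cols])


def order_polar(points: SparsePointSet) -> PolarOrderedPoints:
    """Polar conversion + angular sort; same-angle collisions merge by mean r."""
    theta, radius = to_polar(points.points, points.center)
    if np.all(radius < 1e-12):
        raise DegenerateGeometryError("all points coincide with the center")
    order = np.argsort(theta, kind="stable")
    theta, radius = theta[order], radius[order]
    bins = np.round(theta / _THETA_QUANTUM).astype(np.int64)
    uniq, inverse = np.unique(bins, return_inverse=True)
    if len(uniq) < len(bins):
        theta = np.bincount(inverse, weights=theta) / np.bincount(inverse)
        radius = np.bincount(inverse, weights=radius) / np.bincount(inverse)
    if len(theta) < 3:
        raise DegenerateGeometryError("fewer than 3 distinct angular positions")
    return PolarOrderedPoints(theta=theta, radius=radius, center=points.center)


def linear_interpolant(p0: tuple[float, float], p1: tuple[float, float]):
    """Segment interpolant f(x) through (x0, y0) and (x1, y1).

    f(x) = ((x1 - x) / (x1 - x0)) y0 + ((x - x0) / (x1 - x0)) y1
    """
    x0, y0 = p0
    x1, y1 = p1
    if x1 == x0:
        raise DegenerateGeometryError("segment endpoints share the same abscissa")

    def f(x):
        x = np.asarray(x, dtype=float)
        return ((x1 - x) * y0 + (x - x0) * y1) / (x1 - x0)

    return f


def draw_segment(p0, p1) -> np.ndarray:
    """Rasterize a straight segment by the segment interpolant itself.

    The independent coordinate is the major axis; at every integer step the
    dependent coordinate is the rounded (half-up) value of the linear
    interpolant through the endpoints. Produces an 8-connected line with a
    deterministic, documented rounding convention.
    """
    r0, c0 = int(p0[0]), int(p0[1])
    r1, c1 = int(p1[0]), int(p1[1])
    if abs(c1 - c0) >= abs(r1 - r0):
        if c0 == c1:
            return np.array([[r0, c0]])
        step = 1 if c1 > c0 else -1
        cols = np.arange(c0, c1 + step, step)
        rows = _round_half_up(linear_interpolant((c0, r0), (c1, r1))(cols))
    else:
        step = 1 if r1 > r0 else -1
        rows = np.arange(r0, r1 + step, step)
        cols = _round_half_up(linear_interpolant((r0, c0), (r1, c1))(rows))
    return np.column_stack([rows, cols])


def _rasterize_loop(pixel_pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Union of 8-connected segments joining consecutive points, cyclically."""
    canvas = np.zeros(shape, dtype=bool)
    pts = np.asarray(pixel_pts, dtype=int)
    pts = np.clip(pts, [0, 0], [shape[0] - 1, shape[1] - 1])
    n = len(pts)
    for i in range(n):
        seg = draw_segment(pts[i], pts[(i + 1) % n])
        canvas[seg[:, 0], seg[:, 1]] = True
    return canvas


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (coordinates here are non-negative)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def _finish(raw: np.ndarray, protected: np.ndarray, mode: str) -> ContourLine:
    out = thin_line(raw, protected=protected)
    if not is_closed(out):
        raise DegenerateGeometryError("closed contour could not be formed")
    return ContourLine(out, mode=mode)


def _protected_raster(points: SparsePointSet) -> np.ndarray:
    prot = np.zeros(points.shape, dtype=bool)
    ipts = _round_half_up(points.points)
    keep = (
        (ipts[:, 0] >= 0)
        & (ipts[:, 0] < points.shape[0])
        & (ipts[:, 1] >= 0)
        & (ipts[:, 1] < points.shape[1])
    )
    prot[ipts[keep, 0], ipts[keep, 1]] = True
    return prot


def close_linear(points: SparsePointSet, mode: str = "internal") -> ContourLine:
    """Join consecutive polar-ordered points by straight chords (closed polygon).

    Every input pixel is preserved in the output.
    """
    pop = order_polar(points)
    cart = from_polar(pop.theta, pop.radius, pop.center)
    raw = _rasterize_loop(_round_half_up(cart), points.shape)
    out = raw | _protected_raster(points)
    if not is_closed(out):
        raise DegenerateGeometryError("closed contour could not be formed")
    # the chord union *is* the definition of this closure; no thinning, so
    # the output matches a from-scratch rasterization of the polygon exactly
    return ContourLine(out, mode=mode)


def close_pchip(points: SparsePointSet, mode: str = "internal") -> ContourLine:
    """Shape-preserving closure: monotone cubic interpolation of r(theta).

    The samples are wrapped by appending the first sample at theta + 2*pi, so
    the interpolant is periodic in angle. Monotone runs of r(theta) stay
    monotone (no overshoot), and every input pixel is preserved.
    """
    pop = order_polar(points)
    theta = np.append(pop.theta, pop.theta[0] + 2 * np.pi)
    radius = np.append(pop.radius, pop.radius[0])
    interp = PchipInterpolator(theta, radius)
    r_max = max(float(pop.radius.max()), 1.0)
    n_dense = int(np.ceil(2 * np.pi / (0.5 / r_max))) + 1
    grid = np.union1d(np.linspace(theta[0], theta[-1], n_dense), theta)
    cart = from_polar(grid, interp(grid), pop.center)
    raw = _rasterize_loop(_round_half_up(cart), points.shape)
    prot = _protected_raster(points)
    return _finish(raw | prot, prot, mode)


def _points_raster(points: SparsePointSet) -> np.ndarray:
    canvas = np.zeros(points.shape, dtype=bool)
    ipts = _round_half_up(points.points)
    canvas[
        np.clip(ipts[:, 0], 0, points.shape[0] - 1),
        np.clip(ipts[:, 1], 0, points.shape[1] - 1),
    ] = True
    return canvas


def _collinear(points: np.ndarray) -> bool:
    pts = np.asarray(points, float)
    if len(pts) < 3:
        return True
    v = pts[1:] - pts[0]
    cross = v[0, 0] * v[1:, 1] - v[0, 1] * v[1:, 0]
    return bool(np.all(np.abs(cross) < 1e-9))


def _rough_region(pts_raster: np.ndarray) -> np.ndarray:
    """Close the point cloud morphologically with the smallest radius that
    produces an interior, then erode back; a rough filled-region estimate."""
    for k in range(1, max(pts_raster.shape) // 2):
        footprint = disk_footprint(k)
        dil = ndi.binary_dilation(pts_raster, structure=footprint)
        filled = ndi.binary_fill_holes(dil)
        if (filled & ~dil).sum() > 0.2 * filled.sum():
            return ndi.binary_erosion(filled, structure=footprint, border_value=0)
    return ndi.binary_fill_holes(pts_raster)


def close_active_contour(
    points: SparsePointSet,
    method: str = "chan_vese",
    iterations: int = 100,
    smoothing: int = 1,
    mode: str = "internal",
) -> ContourLine:
    """Close by evolving a morphological active contour onto the points.

    The contour starts at the filled convex hull of the points and evolves
    for ``iterations`` steps; with ``iterations=0`` the hull boundary is
    returned unchanged. Input pixels are not guaranteed preserved.
    """
    if method not in ("chan_vese", "geodesic"):
        raise ValueError(f"method must be 'chan_vese' or 'geodesic', got {method!r}")
    if _collinear(points.points):
        raise DegenerateGeometryError("points are collinear; no enclosed area")
    pts_raster = _points_raster(points)
    init = convex_hull_image(pts_raster)
    if iterations == 0:
        region = init
    elif method == "chan_vese":
        image = gaussian(_rough_region(pts_raster).astype(float), sigma=1)
        region = morphological_chan_vese(
            image, num_iter=iterations, init_level_set=init, smoothing=smoothing
        ).astype(bool)
    else:
        dist = ndi.distance_transform_edt(~pts_raster)
        g = dist**2 / (dist**2 + 9.0)  # ~0 on the points, ~1 far away
        region = morphological_geodesic_active_contour(
            g,
            num_iter=iterations,
            init_level_set=init,
            smoothing=smoothing,
            balloon=-1,
            threshold=0.5,
        ).astype(bool)
    region = ndi.binary_fill_holes(region)
    labels, n = ndi.label(region, structure=np.ones((3, 3), bool))
    if n == 0:
        raise ConvergenceError(
            "active contour collapsed to an empty region; try fewer iterations"
        )
    if n > 1:
        sizes = ndi.sum_labels(region, labels, index=np.arange(1, n + 1))
        region = labels == (1 + int(np.argmax(sizes)))
    line = internal_boundary(region)
    if not is_closed(line):
        raise ConvergenceError("active contour result has no interior")
    return ContourLine(line, mode=mode)


def close_points(
    points: SparsePointSet,
    method: str = "pchip",
    mode: str = "internal",
    iterations: int = 100,
    smoothing: int = 1,
) -> ContourLine:
    """Dispatch to one of the four closing methods by name."""
    if method == "linear":
        return close_linear(points, mode=mode)
    if method == "pchip":
        return close_pchip(points, mode=mode)
    if method in ("chan_vese", "geodesic"):
        return close_active_contour(
            points, method=method, iterations=iterations, smoothing=smoothing, mode=mode
        )
    raise ValueError(f"unknown closing method {method!r}; choose from {CLOSING_METHODS}")


__all__ = [
    "SparsePointSet",
    "PolarOrderedPoints",
    "CLOSING_METHODS",
    "to_polar",
    "from_polar",
    "order_polar",
    "linear_interpolant",
    "close_linear",
    "close_pchip",
    "close_active_contour",
    "close_points",
]
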