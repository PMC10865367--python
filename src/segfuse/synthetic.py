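"""Synthetic ground-truth shapes and simulated raters.

Every fusion algorithm is testable without external data by generating a
known ground-truth region and perturbing it the way human or automatic
annotators disagree:

* ``boundary`` raters displace the boundary radius r(theta) by a smooth,
  zero-mean truncated Fourier series of bounded amplitude — emulating the
  contour-level disagreement between annotators.
* ``bernoulli`` raters corrupt the truth per-pixel with known sensitivity p
  (foreground kept with probability p) and specificity q (background kept
  with probability q) — exactly the generative model the STAPLE consensus
  assumes, so the true (p, q) can be compared with the EM estimates.

All operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import PchipInterpolator
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse, polygon as draw_polygon

from .contour_ops import RegionMask, internal_boundary
from .errors import DegenerateGeometryError, ShapeSpecError
from .mask_io import BinaryMask, SegmentationSet

_EIGHT = np.ones((3, 3), dtype=bool)
_MARGIN = 2  # pixels kept clear of the canvas edge (external lines must fit)


@dataclass(frozen=True)
class ShapeSpec:
    """Ground-truth shape: disk, ellipse, or random smooth blob."""

    kind: str = "disk"
    canvas: tuple[int, int] = (128, 128)
    radius: float = 30.0  # disk
    semi_axes: tuple[float, float] = (30.0, 20.0)  # ellipse (row, col)
    mean_radius: float = 30.0  # blob
    harmonic_amplitude: float = 0.15  # blob: max relative radial modulation
    n_harmonics: int = 4
    seed: int = 0


@dataclass(frozen=True)
class RaterSpec:
    """One simulated annotator.

    ``boundary`` mode: smooth radial displacement of max ``amplitude`` px
    built from ``n_harmonics`` random Fourier components. ``bernoulli``
    mode: per-pixel corruption with sensitivity ``p`` and specificity ``q``.
    """

    mode: str = "boundary"
    amplitude: float = 2.0
    n_harmonics: int = 6
    p: float = 0.9
    q: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("boundary", "bernoulli"):
            raise ShapeSpecError(f"rater mode must be boundary|bernoulli, got {self.mode!r}")
        if self.amplitude < 0:
            raise ShapeSpecError("amplitude must be >= 0")
        if not (0 <= self.p <= 1 and 0 <= self.q <= 1):
            raise ShapeSpecError("p and q must lie in [0, 1]")


def _check_margin(px: np.ndarray, canvas: tuple[int, int]) -> None:
    rows, cols = np.nonzero(px)
    if (
        rows.min() < _MARGIN
        or cols.min() < _MARGIN
        or rows.max() >= canvas[0] - _MARGIN
        or cols.max() >= canvas[1] - _MARGIN
    ):
        raise ShapeSpecError(
            f"shape does not fit the {canvas} canvas with a {_MARGIN}-pixel margin"
        )


def make_shape(spec: ShapeSpec) -> RegionMask:
    """Rasterize the specified shape; deterministic given the seed."""
    h, w = spec.canvas
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    px = np.zeros((h, w), dtype=bool)
    if spec.kind == "disk":
        rr, cc = draw_disk(center, spec.radius, shape=(h, w))
        px[rr, cc] = True
        if center[0] - spec.radius < _MARGIN or center[0] + spec.radius >= h - _MARGIN:
            raise ShapeSpecError(
                f"radius {spec.radius} does not fit the {spec.canvas} canvas "
                f"with a {_MARGIN}-pixel margin"
            )
    elif spec.kind == "ellipse":
        rr, cc = draw_ellipse(center[0], center[1], *spec.semi_axes, shape=(h, w))
        px[rr, cc] = True
    elif spec.kind == "blob":
        rng = np.random.default_rng(spec.seed)
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        mod = _fourier_noise(theta, spec.n_harmonics, rng)
        r = spec.mean_radius * (1.0 + spec.harmonic_amplitude * mod)
        rows = center[0] - r * np.sin(theta)
        cols = center[1] + r * np.cos(theta)
        rr, cc = draw_polygon(rows, cols, shape=(h, w))
        px[rr, cc] = True
    else:
        raise ShapeSpecError(f"unknown shape kind {spec.kind!r}")
    if not px.any():
        raise ShapeSpecError("shape rasterized to an empty mask")
    _check_margin(px, spec.canvas)
    return RegionMask(ndi.binary_fill_holes(px))


def _fourier_noise(theta: np.ndarray, n_harmonics: int, rng) -> np.ndarray:
    """Zero-mean smooth periodic signal, normalized to max |value| = 1."""
    out = np.zeros_like(theta)
    amps = rng.uniform(0.3, 1.0, size=n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    for k in range(1, n_harmonics + 1):
        out += amps[k - 1] * np.cos(k * theta + phases[k - 1])
    peak = np.abs(out).max()
    if peak < 1e-12:
        return np.zeros_like(theta)
    return out / peak


def _radius_profile(region: RegionMask, n_samples: int = 720):
    """Boundary radius r(theta) of a star-shaped region about its centroid."""
    centroid = np.argwhere(region.pixels).mean(axis=0)
    bcoords = np.argwhere(internal_boundary(region.pixels))
    d_row = bcoords[:, 0] - centroid[0]
    d_col = bcoords[:, 1] - centroid[1]
    theta = np.mod(np.arctan2(-d_row, d_col), 2 * np.pi)
    radius = np.hypot(d_row, d_col)
    # bin by angle, keep the outermost boundary pixel per bin
    grid = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    bin_idx = np.floor(theta / (2 * np.pi / n_samples)).astype(int) % n_samples
    r_binned = np.full(n_samples, -np.inf)
    np.maximum.at(r_binned, bin_idx, radius)
    filled = np.isfinite(r_binned)
    if filled.sum() < 8:
        raise DegenerateGeometryError("boundary too small to build a radius profile")
    # periodic interpolation across empty bins
    th = grid[filled]
    rv = r_binned[filled]
    th_wrapped = np.concatenate([th, [th[0] + 2 * np.pi]])
    rv_wrapped = np.concatenate([rv, [rv[0]]])
    interp = PchipInterpolator(th_wrapped, rv_wrapped)
    query = np.where(grid < th[0], grid + 2 * np.pi, grid)
    return centroid, grid, interp(query)


def perturb_boundary(
    region: RegionMask, amplitude: float, n_harmonics: int = 6, seed: int = 0
) -> BinaryMask:
    """Displace the boundary radially by smooth zero-mean noise.

    The displacement is a truncated Fourier series normalized so its maximum
    absolute value equals ``amplitude`` (in pixels). Amplitude 0 returns the
    input unchanged. The region must be star-shaped about its centroid
    (guaranteed for the built-in shape kinds).
    """
    if amplitude < 0:
        raise ShapeSpecError("amplitude must be >= 0")
    if amplitude == 0:
        return BinaryMask(region.pixels.copy(), source=f"boundary-rater(seed={seed})")
    rng = np.random.default_rng(seed)
    centroid, grid, r = _radius_profile(region)
    delta = amplitude * _fourier_noise(grid, n_harmonics, rng)
    r_new = np.maximum(r + delta, 0.5)
    rows = centroid[0] - r_new * np.sin(grid)
    cols = centroid[1] + r_new * np.cos(grid)
    px = np.zeros(region.shape, dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=region.shape)
    px[rr, cc] = True
    if not px.any():
        raise DegenerateGeometryError("perturbation erased the region")
    labels, n = ndi.label(px, structure=_EIGHT)
    if n > 1:
        sizes = ndi.sum_labels(px, labels, index=np.arange(1, n + 1))
        px = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(
        ndi.binary_fill_holes(px), source=f"boundary-rater(seed={seed})"
    )


def bernoulli_votes(region: RegionMask, p: float, q: float, seed: int = 0) -> np.ndarray:
    """Raw per-pixel corruption field (before any cleanup).

    Foreground pixels stay foreground with probability ``p``; background
    pixels stay background with probability ``q``.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(region.shape)
    return np.where(region.pixels, u < p, u >= q)


def _cleanup(raw: np.ndarray) -> np.ndarray:
    """Largest 8-connected component, holes filled (restores mask invariants)."""
    labels, n = ndi.label(raw, structure=_EIGHT)
    if n == 0:
        raise DegenerateGeometryError("corruption erased all foreground")
    sizes = ndi.sum_labels(raw, labels, index=np.arange(1, n + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    return ndi.binary_fill_holes(keep)


def simulate_raters(region: RegionMask, specs: list[RaterSpec]) -> SegmentationSet:
    """Produce one valid mask per rater spec (>= 2 specs required)."""
    masks = []
    for j, spec in enumerate(specs, start=1):
        if spec.mode == "boundary":
            masks.append(
                perturb_boundary(
                    region, spec.amplitude, n_harmonics=spec.n_harmonics, seed=spec.seed
                )
            )
        else:
            raw = bernoulli_votes(region, spec.p, spec.q, seed=spec.seed)
            masks.append(
                BinaryMask(_cleanup(raw), source=f"bernoulli-rater-{j}(seed={spec.seed})")
            )
    return SegmentationSet(tuple(masks))


__all__ = [
    "ShapeSpec",
    "RaterSpec",
    "make_shape",
    "perturb_boundary",
    "bernoulli_votes",
    "simulate_raters",
]
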