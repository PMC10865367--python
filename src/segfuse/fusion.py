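"""The eight fusion algorithms, the dispatcher, and the plugin registry.

Each algorithm consumes a :class:`~segfuse.mask_io.SegmentationSet` and
emits a :class:`~segfuse.contour_ops.ContourLine`:

* ``largest`` — perimeter of the union of all (hole-filled) inputs.
* ``smallest`` — perimeter of the area common to all inputs.
* ``avg_smallest_largest`` — the 1-pixel midline of the band between the
  Smallest and the Largest regions.
* ``avg_target_largest`` / ``avg_target_smallest`` / ``avg_target_input`` —
  per-pixel averaging: walk the target contour, group each target pixel with
  the nearest pixel of every other contour, replace the group by its
  consensus point (midpoint / collinear-extreme midpoint / centroid), then
  close the resulting sparse cloud.
* ``middle`` — iteratively strip the smallest- and largest-area member
  floor((N-1)/2) times; odd N leaves one survivor, even N leaves two that
  are fused by a configurable tiebreak sub-algorithm.
* ``staple`` — EM consensus weighting raters by estimated accuracy.

None of the algorithms is stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage as ndi

from .closing import CLOSING_METHODS, SparsePointSet, close_points
from .contour_ops import (
    LINE_MODES,
    ContourLine,
    RegionMask,
    band_midline,
    extract_line,
    fill_holes,
    region_perimeter,
)
from .errors import (
    ConfigError,
    DegenerateGeometryError,
    EmptyIntersectionError,
    MultiObjectError,
    RegistrationError,
)
from .mask_io import BinaryMask, SegmentationSet
from .staple import RaterPerformance, staple_em

_EIGHT = np.ones((3, 3), dtype=bool)

MIDDLE_TIEBREAKS = ("average", "largest", "smallest")

ALGORITHMS = (
    "largest",
    "smallest",
    "avg_smallest_largest",
    "avg_target_largest",
    "avg_target_smallest",
    "avg_target_input",
    "middle",
    "staple",
)


@dataclass(frozen=True)
class FusionConfig:
    """Algorithm selection plus every tunable the algorithms expose.

    Defaults follow the tool's standard configuration: external one-pixel
    line extraction and shape-preserving (PCHIP) closing.
    """

    algorithm: str = "middle"
    line_mode: str = "external"
    closing: str = "pchip"
    middle_tiebreak: str = "average"
    target_index: int | None = None  # 1-based, avg_target_input only
    staple_max_iter: int = 100
    staple_tol: float = 1e-6
    staple_threshold: float = 0.5
    extra: dict = field(default_factory=dict)  # plugin parameters

    def __post_init__(self) -> None:
        if self.line_mode not in LINE_MODES:
            raise ConfigError(f"line_mode must be one of {LINE_MODES}")
        if self.closing not in CLOSING_METHODS:
            raise ConfigError(f"closing must be one of {CLOSING_METHODS}")
        if self.middle_tiebreak not in MIDDLE_TIEBREAKS:
            raise ConfigError(f"middle_tiebreak must be one of {MIDDLE_TIEBREAKS}")
        if self.staple_max_iter < 1:
            raise ConfigError("staple_max_iter must be positive")
        if self.staple_tol <= 0:
            raise ConfigError("staple_tol must be positive")
        if not 0.0 < self.staple_threshold < 1.0:
            raise ConfigError("staple_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PixelGroup:
    """A target-contour pixel with the nearest pixel of each other contour."""

    target_pixel: tuple[int, int]
    members: tuple[tuple[int, int], ...]


def _filled_regions(segs: SegmentationSet) -> list[np.ndarray]:
    return [ndi.binary_fill_holes(m.pixels) for m in segs]


def _union_region(segs: SegmentationSet) -> RegionMask:
    union = np.logical_or.reduce(_filled_regions(segs))
    _, n = ndi.label(union, structure=_EIGHT)
    if n != 1:
        raise MultiObjectError(
            f"union of the segmentations splits into {n} objects; expected one"
        )
    return fill_holes(union)


def _common_region(segs: SegmentationSet) -> RegionMask:
    counts = np.sum(_filled_regions(segs), axis=0)
    common = counts == segs.n
    if not common.any():
        raise EmptyIntersectionError("the segmentations share no common area")
    _, n = ndi.label(common, structure=_EIGHT)
    if n != 1:
        raise MultiObjectError(
            f"common area splits into {n} objects; expected one"
        )
    return RegionMask(common)


def fuse_largest(segs: SegmentationSet, line_mode: str = "external") -> ContourLine:
    """Perimeter of the union of all hole-filled inputs."""
    return region_perimeter(_union_region(segs), side=line_mode)


def fuse_smallest(segs: SegmentationSet, line_mode: str = "external") -> ContourLine:
    """Perimeter of the area shared by all hole-filled inputs."""
    return region_perimeter(_common_region(segs), side=line_mode)


def fuse_avg_smallest_largest(
    segs: SegmentationSet, line_mode: str = "external"
) -> ContourLine:
    """Midline between the Smallest and Largest regions.

    The band is the Largest region minus the interior of the Smallest (so it
    contains both boundary rings); its distance-transform skeleton, spur-
    pruned, is the 1-pixel middle line. If the two regions coincide the
    common perimeter is returned directly.
    """
    large = _union_region(segs).pixels
    small = _common_region(segs).pixels
    if (large == small).all():
        return region_perimeter(RegionMask(large), side=line_mode)
    cross = ndi.generate_binary_structure(2, 1)
    band = large & ~ndi.binary_erosion(small, structure=cross, border_value=0)
    return ContourLine(band_midline(band), mode=line_mode)


def nearest_member(target_pixel, contour: ContourLine):
    """Contour pixel closest (Euclidean) to ``target_pixel``.

    Ties break toward the smallest row, then the smallest column.
    """
    coords = contour.coords()  # argwhere order is already lexicographic
    d2 = ((coords - np.asarray(target_pixel)) ** 2).sum(axis=1)
    return tuple(coords[int(np.argmin(d2))])


def group_consensus(members) -> tuple[float, float]:
    """Consensus point of a pixel group.

    Two points: their midpoint. More than two, all collinear (exact integer
    cross products): midpoint of the two mutually farthest points. Otherwise:
    arithmetic mean of the member points. The result is continuous.
    """
    pts = np.asarray(members, dtype=np.int64)
    if len(pts) < 2:
        raise DegenerateGeometryError("a pixel group needs at least 2 members")
    if len(pts) == 2:
        mid = pts.mean(axis=0)
        return float(mid[0]), float(mid[1])
    v = pts - pts[0]
    cross = v[:, 0, None] * v[None, :, 1] - v[:, 1, None] * v[None, :, 0]
    if not cross.any():  # all collinear (duplicates included)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
        mid = (pts[i] + pts[j]) / 2.0
        return float(mid[0]), float(mid[1])
    mean = pts.mean(axis=0)
    return float(mean[0]), float(mean[1])


def _nearest_all(target_coords: np.ndarray, contour_coords: np.ndarray) -> np.ndarray:
    """Vectorized nearest_member for every target pixel at once."""
    d2 = (
        (target_coords[:, None, :].astype(np.int64) - contour_coords[None, :, :]) ** 2
    ).sum(axis=-1)
    return contour_coords[np.argmin(d2, axis=1)]


def fuse_avg_target(
    segs: SegmentationSet,
    target: str = "largest",
    target_index: int | None = None,
    line_mode: str = "external",
    closing: str = "pchip",
) -> ContourLine:
    """Per-pixel averaging toward a target contour.

    ``target`` selects the contour the iteration walks: the Largest fusion,
    the Smallest fusion, or one of the inputs (1-based ``target_index``).
    Each target pixel is grouped with the nearest pixel of every other
    contour (the target pixel belongs to its own group), the group is
    replaced by its consensus point, and the resulting sparse point cloud is
    closed with the configured closing method about the centroid of the
    filled union.
    """
    contours = [extract_line(m, mode=line_mode) for m in segs]
    if target == "largest":
        target_line = fuse_largest(segs, line_mode=line_mode)
        others = contours
    elif target == "smallest":
        target_line = fuse_smallest(segs, line_mode=line_mode)
        others = contours
    elif target == "input":
        if target_index is None or not 1 <= target_index <= segs.n:
            raise ConfigError(
                f"target_index must be in 1..{segs.n}, got {target_index}"
            )
        target_line = contours[target_index - 1]
        others = [c for i, c in enumerate(contours) if i != target_index - 1]
    else:
        raise ConfigError(f"target must be largest/smallest/input, got {target!r}")

    tcoords = target_line.coords()
    member_stacks = [_nearest_all(tcoords, c.coords()) for c in others]
    consensus = []
    for k, tpx in enumerate(tcoords):
        members = [tuple(tpx)] + [tuple(stack[k]) for stack in member_stacks]
        consensus.append(group_consensus(members))
    pts = np.floor(np.asarray(consensus) + 0.5).astype(int)  # half-away-from-zero
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"only {len(pts)} distinct consensus pixels; cannot close a contour"
        )
    center = tuple(np.argwhere(_union_region(segs).pixels).mean(axis=0))
    sparse = SparsePointSet(pts, center=center, shape=segs.shape)
    return close_points(sparse, method=closing, mode=line_mode)


def fuse_middle(
    segs: SegmentationSet,
    tiebreak: str = "average",
    line_mode: str = "external",
    info: dict | None = None,
) -> ContourLine:
    """Select the segmentation in the middle of the area ranking.

    floor((N-1)/2) iterations each remove the current smallest- and
    largest-area member (area ties remove the lowest rater index). An odd N
    leaves one survivor whose contour is returned bit-exactly; an even N
    leaves two survivors fused by the ``tiebreak`` sub-algorithm. With N = 2
    and tiebreak "average" the output is identical to avg_smallest_largest.
    """
    if tiebreak not in MIDDLE_TIEBREAKS:
        raise ConfigError(f"tiebreak must be one of {MIDDLE_TIEBREAKS}")
    areas = [int(r.sum()) for r in _filled_regions(segs)]
    remaining = list(range(segs.n))
    iterations = (segs.n - 1) // 2
    for _ in range(iterations):
        smallest = min(remaining, key=lambda i: (areas[i], i))
        remaining.remove(smallest)
        largest = max(remaining, key=lambda i: (areas[i], -i))
        remaining.remove(largest)
    if info is not None:
        info["iterations"] = iterations
        info["survivors"] = [i + 1 for i in remaining]  # 1-based rater ids
    if len(remaining) == 1:
        return extract_line(segs[remaining[0]], mode=line_mode)
    pair = SegmentationSet(tuple(segs[i] for i in remaining))
    if tiebreak == "average":
        return fuse_avg_smallest_largest(pair, line_mode=line_mode)
    if tiebreak == "largest":
        return fuse_largest(pair, line_mode=line_mode)
    return fuse_smallest(pair, line_mode=line_mode)


def fuse_staple(
    segs: SegmentationSet,
    max_iter: int = 100,
    tol: float = 1e-6,
    threshold: float = 0.5,
    line_mode: str = "external",
    info: dict | None = None,
) -> ContourLine:
    """STAPLE consensus: EM-weighted voting over the hole-filled inputs.

    The estimated per-rater performance is reported through ``info``
    (keys ``performance``, ``iterations``, ``converged``).
    """
    votes = np.stack(_filled_regions(segs))
    result = staple_em(
        votes.reshape(segs.n, -1),
        max_iter=max_iter,
        tol=tol,
        threshold=threshold,
    )
    region = (result.weights >= threshold).reshape(segs.shape)
    region = ndi.binary_fill_holes(region)
    labels, n = ndi.label(region, structure=_EIGHT)
    if n > 1:
        warnings.warn(
            f"STAPLE consensus split into {n} components; keeping the largest",
            stacklevel=2,
        )
        sizes = ndi.sum_labels(region, labels, index=np.arange(1, n + 1))
        region = labels == (1 + int(np.argmax(sizes)))
    if info is not None:
        info["performance"] = result.performance
        info["iterations"] = result.iterations
        info["converged"] = result.converged
    return region_perimeter(RegionMask(region), side=line_mode)


# ---------------------------------------------------------------------------
# Dispatcher and plugin registry
# ---------------------------------------------------------------------------

FusionFn = Callable[[SegmentationSet, FusionConfig], ContourLine]

_REGISTRY: dict[str, tuple[FusionFn, dict]] = {}


def register_algorithm(name: str, fn: FusionFn, params_schema: dict | None = None) -> None:
    """Register a fusion algorithm under ``name`` for fuse() and the CLI.

    ``params_schema`` maps parameter names to python types (int, float, str,
    bool); matching keys of ``FusionConfig.extra`` are validated and passed
    through when the algorithm runs.
    """
    if name in _REGISTRY:
        raise RegistrationError(f"algorithm {name!r} is already registered")
    _REGISTRY[name] = (fn, dict(params_schema or {}))


def registered_algorithms() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def validate_params(schema: dict, raw: dict) -> dict:
    """Coerce raw (possibly string-valued) parameters against a schema."""
    out = {}
    for key, typ in schema.items():
        if key not in raw:
            continue
        val = raw[key]
        try:
            if typ is bool and isinstance(val, str):
                if val.lower() in ("true", "1", "yes"):
                    val = True
                elif val.lower() in ("false", "0", "no"):
                    val = False
                else:
                    raise ValueError(val)
            out[key] = typ(val)
        except (TypeError, ValueError):
            raise ConfigError(
                f"parameter {key!r} must be of type {typ.__name__}, got {val!r}"
            ) from None
    return out


def fuse(segs: SegmentationSet, config: FusionConfig) -> ContourLine:
    """Dispatch a segmentation set to the configured fusion algorithm."""
    try:
        fn, schema = _REGISTRY[config.algorithm]
    except KeyError:
        raise ConfigError(
            f"unknown algorithm {config.algorithm!r}; "
            f"registered: {', '.join(registered_algorithms())}"
        ) from None
    if schema:
        config = replace(config, extra=validate_params(schema, config.extra))
    return fn(segs, config)


def _builtin(name):
    def deco(fn):
        register_algorithm(name, fn)
        return fn

    return deco


@_builtin("largest")
def _run_largest(segs, cfg):
    return fuse_largest(segs, line_mode=cfg.line_mode)


@_builtin("smallest")
def _run_smallest(segs, cfg):
    return fuse_smallest(segs, line_mode=cfg.line_mode)


@_builtin("avg_smallest_largest")
def _run_asl(segs, cfg):
    return fuse_avg_smallest_largest(segs, line_mode=cfg.line_mode)


@_builtin("avg_target_largest")
def _run_atl(segs, cfg):
    return fuse_avg_target(
        segs, target="largest", line_mode=cfg.line_mode, closing=cfg.closing
    )


@_builtin("avg_target_smallest")
def _run_ats(segs, cfg):
    return fuse_avg_target(
        segs, target="smallest", line_mode=cfg.line_mode, closing=cfg.closing
    )


@_builtin("avg_target_input")
def _run_ati(segs, cfg):
    return fuse_avg_target(
        segs,
        target="input",
        target_index=cfg.target_index,
        line_mode=cfg.line_mode,
        closing=cfg.closing,
    )


@_builtin("middle")
def _run_middle(segs, cfg):
    return fuse_middle(segs, tiebreak=cfg.middle_tiebreak, line_mode=cfg.line_mode)


@_builtin("staple")
def _run_staple(segs, cfg):
    return fuse_staple(
        segs,
        max_iter=cfg.staple_max_iter,
        tol=cfg.staple_tol,
        threshold=cfg.staple_threshold,
        line_mode=cfg.line_mode,
    )


__all__ = [
    "ALGORITHMS",
    "MIDDLE_TIEBREAKS",
    "FusionConfig",
    "PixelGroup",
    "RaterPerformance",
    "fuse",
    "fuse_largest",
    "fuse_smallest",
    "fuse_avg_smallest_largest",
    "fuse_avg_target",
    "fuse_middle",
    "fuse_staple",
    "nearest_member",
    "group_consensus",
    "register_algorithm",
    "registered_algorithms",
    "validate_params",
    "staple_em",
]
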