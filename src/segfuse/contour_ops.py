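"""Morphological contour primitives.

Conventions: coordinates are (row, col), 0-based, origin at the top-left.
Foreground is 8-connected, background 4-connected (the standard dual pair,
which prevents "leaky" diagonal contours). Boundary adjacency uses
4-neighborhoods, so external rings come out as 8-connected closed loops.

Three one-pixel line flavours are supported for a thick input (see
:func:`extract_line`): the *internal* line (foreground pixels touching
background), the *external* line (background pixels touching foreground),
and the *middle* line (the skeleton of a thick drawn line).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import medial_axis, skeletonize

from .errors import BorderClipError, EmptySegmentationError, TopologyError
from .mask_io import BinaryMask

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity
_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity

LINE_MODES = ("internal", "middle", "external")


@dataclass(frozen=True)
class RegionMask:
    """A hole-filled, single-object foreground region."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels).astype(bool)
        object.__setattr__(self, "pixels", px)
        if not px.any():
            raise EmptySegmentationError("region has no foreground")
        _, n = ndi.label(px, structure=_EIGHT)
        if n != 1:
            raise TopologyError(f"region must be one connected object, found {n}")
        if not (ndi.binary_fill_holes(px) == px).all():
            raise TopologyError("region contains enclosed background (holes)")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ContourLine:
    """A 1-pixel-wide loop of pixels delineating one object boundary.

    ``mode`` records which boundary flavour produced it. Closedness is a
    contract of the producing operations (checked there via
    :func:`is_closed`) rather than of the constructor, because degenerate
    tiny regions legitimately yield perimeter sets with no interior.
    """

    pixels: np.ndarray
    mode: str = "internal"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels).astype(bool)
        object.__setattr__(self, "pixels", px)
        if not px.any():
            raise EmptySegmentationError("contour line has no pixels")
        if self.mode not in LINE_MODES:
            raise ValueError(f"mode must be one of {LINE_MODES}, got {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def coords(self) -> np.ndarray:
        """(K, 2) array of (row, col) foreground coordinates."""
        return np.argwhere(self.pixels)


def _as_array(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "pixels", obj)).astype(bool)


def fill_holes(mask) -> RegionMask:
    """Fill enclosed background: pixels not 4-connected to the border.

    Idempotent; accepts a BinaryMask, ContourLine, RegionMask or bool array.
    """
    return RegionMask(ndi.binary_fill_holes(_as_array(mask)))


def internal_boundary(region) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (canvas edge counts)."""
    px = _as_array(region)
    return px & ~ndi.binary_erosion(px, structure=_CROSS, border_value=0)


def external_boundary(region) -> np.ndarray:
    """Background pixels 4-adjacent to the region."""
    px = _as_array(region)
    return ndi.binary_dilation(px, structure=_CROSS) & ~px


def touches_border(region) -> bool:
    px = _as_array(region)
    return bool(px[0].any() or px[-1].any() or px[:, 0].any() or px[:, -1].any())


def is_closed(line) -> bool:
    """True iff the pixel set encloses at least one background pixel."""
    px = _as_array(line)
    if not px.any():
        return False
    filled = ndi.binary_fill_holes(px)
    return bool((filled & ~px).any())


def is_one_pixel_wide(line) -> bool:
    """True iff the pixel set contains no fully-foreground 2x2 block."""
    px = _as_array(line)
    return not (px[:-1, :-1] & px[1:, :-1] & px[:-1, 1:] & px[1:, 1:]).any()


def prune_spurs(skel: np.ndarray) -> np.ndarray:
    """Iteratively delete endpoint pixels (< 2 8-neighbors) until none remain.

    On a skeleton with a single loop plus spurs this leaves exactly the loop.
    """
    out = _as_array(skel).copy()
    kernel = np.ones((3, 3), dtype=int)
    while True:
        neighbors = ndi.convolve(out.astype(int), kernel, mode="constant") - out
        endpoints = out & (neighbors < 2)
        if not endpoints.any():
            return out
        out &= ~endpoints


# Circular 8-neighborhood order: N, NE, E, SE, S, SW, W, NW.
_NEIGHBOR_OFFSETS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def thin_line(line: np.ndarray, protected: np.ndarray | None = None) -> np.ndarray:
    """Remove redundant pixels from a rasterized curve, keeping it closed.

    Sequential thinning restricted to redundant thickness: only pixels lying
    inside a fully-foreground 2x2 block are candidates, and a candidate is
    deleted when its 8-neighborhood foreground forms a single circular arc
    (one 0-to-1 transition) of 2..7 pixels, which preserves local
    connectivity and never opens an enclosed region. Restricting candidates
    to 2x2 blocks leaves clean 1-pixel loops untouched (their corners are
    not shaved). Pixels in ``protected`` are never deleted, which lets
    closing methods keep every original input pixel while still flattening
    thick joints between chords.
    """
    out = np.asarray(line).astype(bool).copy()
    prot = np.zeros_like(out) if protected is None else np.asarray(protected, bool)
    h, w = out.shape
    changed = True
    while changed:
        changed = False
        blocks = out[:-1, :-1] & out[1:, :-1] & out[:-1, 1:] & out[1:, 1:]
        in_block = np.zeros_like(out)
        in_block[:-1, :-1] |= blocks
        in_block[1:, :-1] |= blocks
        in_block[:-1, 1:] |= blocks
        in_block[1:, 1:] |= blocks
        for r, c in np.argwhere(out & in_block & ~prot):
            ring = [
                bool(out[r + dr, c + dc])
                if 0 <= r + dr < h and 0 <= c + dc < w
                else False
                for dr, dc in _NEIGHBOR_OFFSETS
            ]
            b = sum(ring)
            if not 2 <= b <= 7:
                continue
            transitions = sum(
                (not ring[i]) and ring[(i + 1) % 8] for i in range(8)
            )
            if transitions == 1:
                out[r, c] = False
                changed = True
    return out


def extract_line(mask, mode: str = "internal") -> ContourLine:
    """Extract a 1-pixel boundary line from a filled region or thick line.

    ``internal``: foreground pixels of the hole-filled mask 4-adjacent to
    background. ``external``: background ring 4-adjacent to the filled mask
    (errors if the object touches the canvas edge). ``middle``: skeleton of
    the original *unfilled* thick line, spur-pruned to a closed loop; on a
    filled blob with no annulus structure it degrades to ``internal`` with a
    warning, since thickness is undefined there.
    """
    if mode not in LINE_MODES:
        raise ValueError(f"mode must be one of {LINE_MODES}, got {mode!r}")
    px = _as_array(mask)
    if mode == "middle":
        filled = ndi.binary_fill_holes(px)
        if (filled == px).all():
            warnings.warn(
                "middle line requested on a filled region with no annulus "
                "structure; falling back to the internal line",
                stacklevel=2,
            )
            return ContourLine(internal_boundary(filled), mode="middle")
        skel = prune_spurs(skeletonize(px))
        if not skel.any() or not is_closed(skel):
            raise TopologyError("skeleton cannot be pruned to a closed loop")
        return ContourLine(skel, mode="middle")
    region = fill_holes(px)
    return region_perimeter(region, side=mode)


def region_perimeter(region: RegionMask, side: str = "internal") -> ContourLine:
    """Boundary ring of a filled region, on the requested side."""
    if side == "middle":
        side = "internal"
    if side == "internal":
        return ContourLine(internal_boundary(region), mode="internal")
    if side == "external":
        if touches_border(region):
            raise BorderClipError(
                "external boundary would leave the canvas: region touches the border"
            )
        return ContourLine(external_boundary(region), mode="external")
    raise ValueError(f"side must be 'internal' or 'external', got {side!r}")


def band_midline(band: np.ndarray) -> np.ndarray:
    """Closed 1-pixel midline of a closed band (annulus-like region).

    Uses the distance-transform skeleton (medial axis) followed by spur
    pruning; the result for an annulus is the ring at the medial radius.
    The medial-axis tie-break order is seeded so the operation is a pure
    function of its input.
    """
    skel = prune_spurs(medial_axis(band, rng=0))
    if not skel.any() or not is_closed(skel):
        raise TopologyError("band midline is not a closed loop")
    return skel


__all__ = [
    "RegionMask",
    "ContourLine",
    "LINE_MODES",
    "fill_holes",
    "internal_boundary",
    "external_boundary",
    "touches_border",
    "is_closed",
    "is_one_pixel_wide",
    "prune_spurs",
    "thin_line",
    "extract_line",
    "region_perimeter",
    "band_midline",
]
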