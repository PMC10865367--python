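"""Reading, validating and writing binary segmentation masks.

A segmentation is a rectangular binary image whose foreground marks a single
object, drawn either as a filled region or as a (possibly thick) closed line.
Foreground is strictly ``value > 0`` after collapsing RGB to luminance, so
both ``{0, 1}`` and ``{0, 255}`` conventions load identically.

Supported raster formats: PNG, TIFF (single page) and BMP, 8- or 16-bit,
single-channel or RGB(A).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .errors import (
    ArityError,
    EmptySegmentationError,
    MaskFormatError,
    MultiObjectError,
    ShapeMismatchError,
)

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element

# ITU-R BT.601 luma weights; for masks with equal channels the result is the
# channel value itself, so the >0 rule is unaffected by the weighting.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BinaryMask:
    """One rater's binary segmentation of a single object.

    Invariants (checked on construction): at least one foreground pixel and
    exactly one 8-connected foreground component after hole filling.
    """

    pixels: np.ndarray
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise MaskFormatError(f"mask must be 2-D, got shape {px.shape}")
        px = px.astype(bool)
        object.__setattr__(self, "pixels", px)
        where = f" in {self.source}" if self.source else ""
        if not px.any():
            raise EmptySegmentationError(f"no foreground pixels{where}")
        filled = ndi.binary_fill_holes(px)
        _, n_comp = ndi.label(filled, structure=_EIGHT)
        if n_comp != 1:
            raise MultiObjectError(
                f"expected one foreground object, found {n_comp}{where}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SegmentationSet:
    """Ordered collection of same-shape masks; index identifies the rater.

    Rater indices are 1-based in user-facing messages.
    """

    masks: tuple[BinaryMask, ...]

    def __post_init__(self) -> None:
        masks = tuple(self.masks)
        object.__setattr__(self, "masks", masks)
        if len(masks) < 2:
            raise ArityError(f"a segmentation set needs >= 2 masks, got {len(masks)}")
        ref = masks[0]
        for i, m in enumerate(masks[1:], start=2):
            if m.shape != ref.shape:
                a = ref.source or "mask 1"
                b = m.source or f"mask {i}"
                raise ShapeMismatchError(
                    f"dimension mismatch: {a} is {ref.shape}, {b} is {m.shape}"
                )

    @property
    def n(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[0].shape

    def __iter__(self):
        return iter(self.masks)

    def __getitem__(self, i: int) -> BinaryMask:
        return self.masks[i]


def _to_gray(arr: np.ndarray, path: str) -> np.ndarray:
    """Collapse a decoded raster to a 2-D grayscale array."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return np.asarray(arr[..., :3], dtype=float) @ _LUMA
    if arr.ndim == 3:
        raise MaskFormatError(
            f"{path}: multi-page/volumetric images are not supported "
            "(the tool consumes independent 2-D sections)"
        )
    raise MaskFormatError(f"{path}: unsupported image layout {arr.shape}")


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Load a raster file as a :class:`BinaryMask` (foreground = value > 0)."""
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise MaskFormatError(f"file not found: {path}") from None
    except Exception as exc:  # decoder errors vary by plugin
        raise MaskFormatError(f"cannot decode {path}: {exc}") from exc
    gray = _to_gray(np.asarray(arr), path)
    return BinaryMask(gray > 0, source=path)


def write_mask(mask, path: str | os.PathLike) -> None:
    """Write a mask or contour raster as an 8-bit image (255 = foreground).

    Round-trips bit-exactly through :func:`read_mask` for PNG/TIFF/BMP.
    """
    px = np.asarray(getattr(mask, "pixels", mask)).astype(bool)
    if px.ndim != 2:
        raise MaskFormatError(f"mask must be 2-D, got shape {px.shape}")
    if not px.any():
        raise EmptySegmentationError("refusing to write an empty mask")
    path = os.fspath(path)
    try:
        iio.imwrite(path, (px.astype(np.uint8) * 255))
    except Exception as exc:
        raise MaskFormatError(f"cannot write {path}: {exc}") from exc


def load_set(paths: list[str | os.PathLike]) -> SegmentationSet:
    """Load >= 2 mask files, in order, into a dimension-checked set."""
    if len(paths) < 2:
        raise ArityError(f"need at least 2 segmentations, got {len(paths)}")
    return SegmentationSet(tuple(read_mask(p) for p in paths))
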