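import numpy as np
import pytest

from segfuse import BinaryMask, RaterSpec, SegmentationSet, ShapeSpec, make_shape, simulate_raters


def square(canvas: int, top: int, left: int, size: int) -> np.ndarray:
    px = np.zeros((canvas, canvas), dtype=bool)
    px[top : top + size, left : left + size] = True
    return px


def disk(canvas: int, center, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[:canvas, :canvas]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def disk_truth():
    """Radius-20 disk on a 64x64 canvas: the standard synthetic ground truth."""
    return make_shape(ShapeSpec(kind="disk", canvas=(64, 64), radius=20))


@pytest.fixture(scope="session")
def boundary_set(disk_truth):
    """Five boundary raters (amplitude 2 px) around the standard disk."""
    specs = [RaterSpec(mode="boundary", amplitude=2, seed=s) for s in range(5)]
    return simulate_raters(disk_truth, specs)


@pytest.fixture
def nested_squares():
    """Concentric filled squares, 5x5 inside 9x9, on an 13x13 canvas."""
    outer = BinaryMask(square(13, 2, 2, 9))
    inner = BinaryMask(square(13, 4, 4, 5))
    return SegmentationSet((inner, outer))
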