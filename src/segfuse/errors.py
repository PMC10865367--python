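"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`SegfuseError`
so the CLI can catch one type, print the message, and exit nonzero.
"""


class SegfuseError(Exception):
    """Base class for all segfuse errors."""


class MaskFormatError(SegfuseError):
    """File could not be read/decoded as a supported raster image."""


class EmptySegmentationError(SegfuseError):
    """A mask contains no foreground pixels."""


class MultiObjectError(SegfuseError):
    """More than one 8-connected foreground object where one is required."""


class ShapeMismatchError(SegfuseError):
    """Masks in a set do not share identical dimensions."""


class ArityError(SegfuseError):
    """Fewer inputs than an operation requires (e.g. a set needs >= 2)."""


class TopologyError(SegfuseError):
    """A contour could not be reduced to a single closed 1-pixel loop."""


class BorderClipError(SegfuseError):
    """An external boundary ring would leave the image canvas."""


class DegenerateGeometryError(SegfuseError):
    """Point geometry too degenerate to close (collinear, coincident...)."""


class EmptyIntersectionError(SegfuseError):
    """The common area of all segmentations is empty."""


class ConvergenceError(SegfuseError):
    """An iterative scheme collapsed or failed to produce a usable result."""


class DegenerateVoteError(SegfuseError):
    """Voting produced an all-foreground or all-background reference."""


class RegistrationError(SegfuseError):
    """Algorithm registry conflict (duplicate name)."""


class ConfigError(SegfuseError):
    """Invalid fusion configuration or unknown algorithm name."""


class UndefinedScoreError(SegfuseError):
    """A similarity score is undefined (e.g. Jaccard of two empty sets)."""


class ShapeSpecError(SegfuseError):
    """A synthetic shape specification violates its constraints."""
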