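"""Exception hierarchy shared across the package.

Every error raised by nucleoquant derives from :class:`NucleoquantError`
so callers can catch the package's failures with a single clause.
"""


class NucleoquantError(Exception):
    """Base class for all nucleoquant errors."""


# --- synthetic scene generation ---------------------------------------------

class InvalidSpec(NucleoquantError):
    """A scene/trace specification violates its invariants."""


class PlacementInfeasible(NucleoquantError):
    """Objects could not be placed without overlap within the retry budget."""


# --- images and masks --------------------------------------------------------

class ChannelNotFound(NucleoquantError, KeyError):
    """Requested channel name is not present in the image."""


class MaskMismatch(NucleoquantError):
    """A label mask does not share the spatial shape of its image."""


class NoSeeds(NucleoquantError):
    """Secondary-object segmentation was given an empty seed mask."""


class DegenerateObject(NucleoquantError):
    """An object is too small for the requested texture measurement."""


class TooFewCells(NucleoquantError):
    """A per-condition summary needs at least two cells per condition."""


# --- polysome traces ---------------------------------------------------------

class ParseError(NucleoquantError):
    """A trace file could not be parsed as two numeric columns."""


class NonMonotonicX(NucleoquantError):
    """Trace x values are not strictly increasing."""


class TooFewPeaks(NucleoquantError):
    """Fewer detectable peaks than required to anchor the profile."""


class NoValley(NucleoquantError):
    """No interior minimum exists between two detected peaks."""


class DegenerateTrace(NucleoquantError):
    """Trace has zero dynamic range (max == min)."""


class EmptyWindow(NucleoquantError):
    """An integration window contains too few samples."""


# --- reporting ---------------------------------------------------------------

class MissingControl(NucleoquantError):
    """The designated control condition has no rows."""


class NonPositiveControlMean(NucleoquantError):
    """Control mean must be positive to define fold changes."""


class TooFewValues(NucleoquantError):
    """Each group in a two-sample test needs at least two values."""


class DivisionByZero(NucleoquantError):
    """Denominator of a ratio statistic is zero."""
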