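"""Exception types raised by the ciquant pipeline.

Each condition the pipeline treats as "not a number" (an excluded slide, a
degenerate threshold input, an impossible object packing) gets its own class
so callers can discriminate without string matching.
"""


class CiquantError(Exception):
    """Base class for all ciquant-specific errors."""


class PackingError(CiquantError):
    """Requested objects cannot be placed at the required minimum separation."""


class DegenerateInputError(CiquantError):
    """Input has no structure to operate on (e.g. constant image for Otsu)."""


class ExcludedSlideError(CiquantError):
    """Slide cannot be CI-scored (no adipose tissue in the section)."""


class EmptyRegionError(CiquantError):
    """A region filter left no cells/pixels to quantify."""


class DegenerateSplitError(CiquantError):
    """Median dichotomization impossible (all values identical)."""


class UndefinedHazardRatioError(CiquantError):
    """O/E hazard ratio undefined (a group has zero expected events)."""
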