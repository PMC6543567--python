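"""Exception hierarchy.

All domain failures derive from :class:`UriStripError` so callers (and the
CLI) can distinguish domain errors from programming errors.
"""


class UriStripError(Exception):
    """Base class for all domain errors raised by this package."""


class SpecificationError(UriStripError, ValueError):
    """An input object violates its stated invariants (bad geometry, bad
    parameters, non-monotone hue scales, illegal log patterns...)."""


class RoiBoundsError(UriStripError, ValueError):
    """A region of interest does not lie inside its parent image."""


class UnusableReferenceError(UriStripError):
    """The white-reference image is too dark to estimate channel gains."""


class CalibrationError(UriStripError):
    """A calibration step failed (missing titration level, non-monotone
    level means, ...)."""


class PadNotFoundError(UriStripError):
    """No reagent-pad contour survived edge detection and area filtering."""


class SamplingError(UriStripError):
    """The pad center region cannot supply the requested sample count."""


class HueWrapError(SamplingError):
    """Sampled hues fall too close to the 0/360 deg wrap point for an
    arithmetic mean to be meaningful."""


class InsufficientFramesError(UriStripError):
    """Fewer frames were supplied than the analysis is configured to use."""


class DuplicateEntryError(UriStripError):
    """An identical reading (same date, time and category) already exists."""


class PairingError(UriStripError, ValueError):
    """Paired category lists have mismatched lengths or are empty."""


class UndefinedKappaError(UriStripError):
    """Chance agreement is 1 (a single shared category), so kappa has a
    zero denominator and is undefined."""
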