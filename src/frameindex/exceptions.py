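"""Exception hierarchy shared across the package.

Errors are split by origin so callers (and the CLI exit codes) can
distinguish configuration mistakes, malformed data/designs, and numerical
degeneracies.
"""


class FrameindexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FrameindexError):
    """An invalid configuration value; the message names the field."""


class SizeError(FrameindexError):
    """Inputs too small or with mismatched shapes for the operation."""


class DesignError(FrameindexError):
    """The trial design does not support the requested analysis
    (missing direction labels, single posture, ...)."""


class CrossValidationError(FrameindexError):
    """Not enough runs to build the requested cross-validation folds."""


class PairingError(FrameindexError):
    """Paired inputs of unequal length."""


class DegenerateBaselineError(FrameindexError):
    """A voxel's rest-period baseline is too close to zero to normalize by."""


class BoundaryError(FrameindexError):
    """A trial block extends past the end of its run series."""


class UntunedError(FrameindexError):
    """A cosine fit flagged as untuned was used where a preferred
    direction is required."""


class UndefinedMeanError(FrameindexError):
    """Circular mean direction undefined (zero resultant vector)."""
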