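"""Exception types raised across the package."""


class MMAlignError(Exception):
    """Base class for all package-specific errors."""


class TooFewLandmarksError(MMAlignError):
    """Raised when an image yields too few landmarks to match or fit."""


class SingularSystemError(MMAlignError):
    """Raised when a linear system is singular (e.g. ridge weight 0 with
    rank-deficient features); the message names the remedy."""


class DegenerateFitError(MMAlignError):
    """Raised when a spatial-transform fit is under-determined."""


class NumericalError(MMAlignError):
    """Raised when an optimisation encounters non-finite values."""
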