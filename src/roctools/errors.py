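"""Exception hierarchy shared across the package."""


class ROCToolsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ROCToolsError, ValueError):
    """Raised when user input violates a precondition (bad labels, empty class, ...)."""


class EstimationError(ROCToolsError, RuntimeError):
    """Raised when a statistic cannot be estimated (zero variance, all-NaN replicates, ...)."""


class FitError(EstimationError):
    """Raised when a smoothing fit fails (too few points, incompatible support, ...)."""
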