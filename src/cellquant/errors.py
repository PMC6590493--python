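"""Exception hierarchy for cellquant."""


class CellquantError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CellquantError, ValueError):
    """Malformed data passed to an operation (wrong shape, range, or dtype)."""


class InvalidParameterError(CellquantError, ValueError):
    """A parameter outside its documented range."""


class DegenerateImageError(CellquantError):
    """Image has too little stained tissue (or a rank-deficient stain plane)
    for stain estimation; callers normally skip normalization for the patch."""


class ContractViolationError(CellquantError):
    """A pluggable component (e.g. a feature extractor) broke its contract."""


class InvalidTrainingSetError(CellquantError, ValueError):
    """Training data cannot support the requested fit (e.g. one class only)."""


class UndefinedMetricError(CellquantError):
    """The requested statistic is undefined on this input (zero variance,
    all-tied ranks, ...)."""


class UnstableCIError(CellquantError):
    """Too many degenerate bootstrap resamples to report an interval."""


class EmptyPairSetError(CellquantError, ValueError):
    """No adjacent-level pairs can be formed from the given levels."""


class PlacementFailureError(CellquantError):
    """Synthetic nucleus placement could not reach the target area fraction."""


class ConfigurationError(CellquantError, ValueError):
    """Inconsistent or infeasible pipeline configuration."""


class BundleError(CellquantError, IOError):
    """A model bundle could not be read, or its version is unsupported."""
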