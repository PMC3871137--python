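"""Exception hierarchy for the nirshelf pipeline.

Validation errors (bad configuration, malformed files, violated
preconditions) derive from :class:`ValidationError`; failures arising
during numerical work derive from :class:`ComputationError`.  The CLI
maps the two branches to distinct exit codes.
"""


class NirshelfError(Exception):
    """Base class for all package errors."""


class ValidationError(NirshelfError):
    """Invalid input, configuration or file format."""


class ComputationError(NirshelfError):
    """A numerical procedure failed on otherwise valid input."""


class FormatError(ValidationError):
    """Malformed spectra/manifest file (ragged rows, bad cells, bad grid)."""


class GridMismatchError(ValidationError):
    """Spectra or models refer to incompatible wavenumber grids."""


class EmptyRegionError(ValidationError):
    """A spectral region does not overlap the grid."""


class ConfigError(ValidationError):
    """Synthetic-study or run configuration violates its invariants."""


class InvalidRecordError(ValidationError):
    """A titration record violates its physical constraints."""


class SplitError(ValidationError):
    """Calibration/prediction split cannot be formed."""


class FilterSizeError(ValidationError):
    """Savitzky-Golay window exceeds the spectrum length."""


class InsufficientSetError(ValidationError):
    """Too few spectra to derive a set-based reference (e.g. MSC mean)."""


class DomainError(ValidationError):
    """Argument outside a model's domain (e.g. negative storage time)."""


class SelectionError(ComputationError):
    """Wavenumber selection found fewer candidates than requested."""


class CollinearityError(ComputationError):
    """Regression design matrix is rank deficient."""


class DegenerateFitError(ComputationError):
    """A per-spectrum fit degenerated (e.g. MSC slope ~ 0)."""


class FitFailureError(ComputationError):
    """Iterative model fitting failed to converge."""


class NonInvertibleError(ComputationError):
    """Kinetic model cannot be inverted for storage time (rate = 0)."""


class NonDegradingError(ComputationError):
    """Shelf-life computation requires a strictly positive decay rate."""
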