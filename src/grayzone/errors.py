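"""Exception hierarchy.

Input-data problems (schema, ranges, duplicates) and configuration problems
are kept distinct because the command-line interface maps them to different
exit codes (2 and 3 respectively).
"""


class GrayzoneError(Exception):
    """Base class for all package errors."""


class InputError(GrayzoneError):
    """A problem with user-supplied data files (CLI exit code 2)."""


class SchemaError(InputError):
    """A required column is missing or the header is malformed."""


class DataValidationError(InputError):
    """A parsed value violates its contract (range, positivity, ...)."""


class DuplicateError(InputError):
    """A key that must be unique occurs more than once."""


class ConfigError(GrayzoneError):
    """Invalid configuration (CLI exit code 3)."""


class InsufficientDataError(GrayzoneError):
    """Too few samples/runs for the requested computation."""


class SingularCovarianceError(GrayzoneError):
    """Sample covariance not invertible; rerun with pseudo_inverse=True."""


class DegenerateCovariateError(GrayzoneError):
    """A model covariate is constant and its effect is inestimable."""


class ComparabilityError(GrayzoneError):
    """Nested-model comparison attempted across different subject sets."""
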