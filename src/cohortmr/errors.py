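"""Exception hierarchy shared across the package."""


class CohortMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CohortMRError):
    """A simulation or run configuration violates its invariants."""


class DomainError(CohortMRError):
    """An input value lies outside the mathematical domain of an operation."""


class InputError(CohortMRError):
    """Malformed or inconsistent input data (lengths, duplicates, schema)."""


class EmptyInputError(InputError):
    """An operation received no usable records."""


class DegenerateQuartileError(DomainError):
    """Exposure has no variation: quartile cutpoints are not distinct."""


class SeparationError(CohortMRError):
    """Complete separation detected while fitting a logistic model."""


class InsufficientInstrumentsError(InputError):
    """Too few genetic instruments for the requested MR estimator."""


class PipelineError(CohortMRError):
    """A pipeline stage failed; downstream stages were skipped."""
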