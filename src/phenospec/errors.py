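"""Exception hierarchy shared across the pipeline stages."""


class PhenospecError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhenospecError):
    """An invalid configuration value (bad grid, non-positive counts, ...)."""


class ValidationError(PhenospecError):
    """Input data violates a stage precondition."""


class DegenerateInputError(ValidationError):
    """A statistic is undefined for this input (zero variance, zero mean, ...)."""
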