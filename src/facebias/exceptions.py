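"""Exception hierarchy for the facebias pipeline."""


class FaceBiasError(Exception):
    """Base class for all facebias errors."""


class ConfigurationError(FaceBiasError):
    """An invalid simulation or analysis configuration field."""


class SchemaError(FaceBiasError):
    """An input table is missing required columns."""


class ValidationError(FaceBiasError):
    """An input table contains invalid rows or values."""


class DegenerateInputError(FaceBiasError):
    """Input is formally valid but statistically degenerate
    (too few observations, zero variance, constant predictor)."""
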