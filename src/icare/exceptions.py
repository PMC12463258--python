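"""Exception hierarchy shared across the package."""


class ICareError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ICareError, ValueError):
    """A run was configured inconsistently (bad flag, bad column name, bad spec)."""


class ValidationError(ICareError, ValueError):
    """Input data violated an invariant (missing values, non-binary outcome, ...)."""


class UnknownFeatureError(ValidationError):
    """A patient record referenced a feature absent from the case pool."""


class DegenerateTrainingError(ICareError, RuntimeError):
    """A model fit was impossible, e.g. only one outcome class present."""
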