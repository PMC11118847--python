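"""Exception hierarchy shared across the package."""


class LpoagreeError(Exception):
    """Base class for all package-specific errors."""


class InvalidDenominatorError(LpoagreeError):
    """A 220 nm absorbance (the per-phase ratio denominator) is zero or negative."""


class DegenerateDataError(LpoagreeError):
    """Input has zero variance where a statistic requires spread."""


class InsufficientDataError(LpoagreeError):
    """Too few observations for the requested statistic."""


class ConfigError(LpoagreeError):
    """Invalid simulation or pipeline configuration; message lists offending fields."""


class InfeasibleODError(LpoagreeError):
    """A target concentration implies an absorbance above the configured cap."""


class SchemaError(LpoagreeError):
    """An input table does not match the expected column schema."""
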