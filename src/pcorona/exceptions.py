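"""Exception hierarchy used across the package."""


class PcoronaError(Exception):
    """Base class for all package errors."""


class SchemaError(PcoronaError):
    """A declared column is missing or column roles are inconsistent."""


class ParseError(PcoronaError):
    """A cell could not be parsed to the declared type."""


class CompletenessError(PcoronaError):
    """The table contains missing values; the pipeline assumes complete data."""


class DimensionError(PcoronaError):
    """Array shapes are mutually inconsistent."""


class ConfigError(PcoronaError):
    """An invalid configuration value."""


class DegenerateInputError(PcoronaError):
    """Input whose statistic is undefined (e.g. constant vector)."""


class TrainingError(PcoronaError):
    """Model training preconditions not met."""
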