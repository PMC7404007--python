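"""Exception hierarchy for the staging engine."""


class MetastageError(Exception):
    """Base class for all errors raised by metastage."""


class ConfigError(MetastageError):
    """Problem with the declarative staging configuration."""


class ConfigParseError(ConfigError):
    """The configuration document is not syntactically well-formed."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(message + loc)


class ConfigSchemaError(ConfigError):
    """The configuration violates the schema or an invariant."""


class IngestError(MetastageError):
    """Raised when an input file cannot be read or parsed."""


class EncodingDetectionError(IngestError):
    """No candidate encoding decodes the input bytes."""


class TimestampError(MetastageError):
    """A timestamp token could not be parsed under the configured conventions."""


class EmitError(MetastageError):
    """A staging bundle cannot be produced (e.g. nothing loadable)."""


class BundleExistsError(EmitError):
    """Refusing to overwrite a non-empty output directory without --force."""


class StrictModeError(MetastageError):
    """A warning-level anomaly occurred while running in strict mode."""
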