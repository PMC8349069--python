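"""Exception types shared across the package."""


class CernaxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CernaxError):
    """A configuration value is invalid; ``field`` names the offender."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class ParseError(CernaxError):
    """A file could not be parsed; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PrerequisiteError(CernaxError):
    """A pipeline stage was invoked before the stage it depends on."""
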