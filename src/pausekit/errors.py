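"""Exception hierarchy shared across the package."""


class PausekitError(Exception):
    """Base class for all pausekit errors."""


class ParseError(PausekitError):
    """A text input (BED/GTF/TSV) failed to parse.

    Carries the 1-based line number when known so the offending record
    can be located in the source file.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ConfigError(PausekitError):
    """A configuration value or schema violation; names the field path."""


class DataError(PausekitError):
    """Inputs parsed but are scientifically unusable (empty, degenerate, mismatched)."""
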