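"""Exception types shared across the package."""


class MarkspreadError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MarkspreadError, ValueError):
    """A parameter set violates one of its invariants.

    The message names the violated invariant so that a bad config file or
    CLI flag can be fixed without reading source code.
    """


class ParseError(MarkspreadError, ValueError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line
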