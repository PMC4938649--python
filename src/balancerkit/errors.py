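"""Exception hierarchy for balancerkit."""


class BalancerKitError(Exception):
    """Base class for all balancerkit errors."""


class InvalidCoordinateError(BalancerKitError):
    """A coordinate is outside the valid 1-based range."""


class InvalidIntervalError(BalancerKitError):
    """An interval's right bound precedes its left bound."""


class InvalidEventError(BalancerKitError):
    """A rearrangement event is out of bounds or internally unordered."""


class InvalidConfigError(BalancerKitError):
    """A simulation or pipeline configuration is inconsistent."""


class ParseError(BalancerKitError):
    """A text input (BED/TSV/config) could not be parsed."""

    def __init__(self, message: str, filename: str | None = None,
                 lineno: int | None = None):
        loc = ""
        if filename is not None:
            loc = f" [{filename}" + (f":{lineno}" if lineno else "") + "]"
        super().__init__(message + loc)
        self.filename = filename
        self.lineno = lineno
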