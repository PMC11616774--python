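"""Exception hierarchy for model parsing and analysis."""


class GatekeeprError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GatekeeprError):
    """The input violates the structural conventions of its file format."""


class ExpressionParseError(FormatError):
    """A Boolean rule expression could not be parsed.

    Carries ``line`` (1-based input line number) when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnresolvedSymbolError(GatekeeprError):
    """A rule references a node that has no definition in the model."""


class UnsupportedModelError(GatekeeprError):
    """The model uses features outside the Boolean (two-level) fragment."""


class UnsupportedConstructError(UnsupportedModelError):
    """A rule uses a construct (e.g. arithmetic MathML) with no Boolean meaning."""


class CapacityError(GatekeeprError):
    """The exhaustive dynamics oracle was asked for a state space too large."""
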