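"""Exception hierarchy shared across the pipeline stages."""


class ChemonetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ChemonetError, ValueError):
    """An invalid configuration field (names the offending field)."""


class InputError(ChemonetError, ValueError):
    """Malformed or out-of-contract input data."""


class StructuralError(ChemonetError, ValueError):
    """A table is missing rows the contract requires (e.g. untreated controls)."""


class ParseError(ChemonetError, ValueError):
    """A text input could not be parsed; carries a line number where possible."""


class DegenerateReferenceError(ChemonetError, ValueError):
    """The wild-type reference has zero fitness and cannot normalize."""


class DegenerateProfileError(ChemonetError, ValueError):
    """A profile has zero variance; correlation is undefined."""
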