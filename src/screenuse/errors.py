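"""Exception hierarchy for the screenuse package."""


class ScreenUseError(Exception):
    """Base class for all errors raised by screenuse."""


class InputError(ScreenUseError):
    """A required input file is missing or unreadable."""


class DialectError(ScreenUseError):
    """The configured column mapping does not match the file."""


class EmptyInputError(ScreenUseError):
    """A file parsed cleanly but contained zero usable rows."""


class SchemaError(ScreenUseError):
    """A table has the wrong shape (e.g. wrong number of item columns)."""


class ValidationError(ScreenUseError):
    """Row-level content violates a declared invariant."""


class ConfigError(ScreenUseError):
    """An analysis or simulation parameter is out of its valid range."""


class SimulationError(ScreenUseError):
    """The requested synthetic cohort cannot be generated as configured."""
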