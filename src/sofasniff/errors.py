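"""Exception types shared across the package."""


class SofaSniffError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SofaSniffError, ValueError):
    """A value violates an operation's precondition."""


class UnknownVariableError(SofaSniffError, ValueError):
    """An observation names a variable the engine does not know."""


class UnitError(SofaSniffError, ValueError):
    """An observation's unit string does not match the variable's declared unit."""


class ConfigError(SofaSniffError, ValueError):
    """A configuration file or value is invalid."""
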