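"""Exception hierarchy shared across the package."""


class ModelbenchError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ModelbenchError, ValueError):
    """An argument violates a documented precondition."""


class UnknownModelError(ModelbenchError, KeyError):
    """A model name is not in the 88-model registry."""


class ParseError(ModelbenchError, ValueError):
    """A file could not be parsed; the message names the offending record."""


class NumericError(ModelbenchError, ArithmeticError):
    """A likelihood computation produced a non-finite intermediate."""
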