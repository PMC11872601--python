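"""Exception hierarchy shared across the package."""


class SigEvalError(Exception):
    """Base class for all package-specific failures."""


class ParseError(SigEvalError):
    """A file could not be parsed; the message names the offending location."""


class DataError(SigEvalError):
    """Input data violate a precondition (duplicate ids, bad shapes, ...)."""


class UndefinedScoreError(SigEvalError):
    """A score cannot be computed for this input (e.g. no usable genes)."""


class InsufficientGenesError(UndefinedScoreError):
    """Too few gene values for the requested score (IQM needs at least four)."""
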