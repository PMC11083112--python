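"""Exception hierarchy shared across the package."""


class GlycostdError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GlycostdError):
    """A structure or table file could not be parsed."""


class TopologyError(GlycostdError):
    """Frames of one ensemble disagree on atom identity or order."""


class SelectionError(GlycostdError):
    """An atom selection expression is invalid or ambiguous."""


class ValidationError(GlycostdError):
    """Input values violate a documented precondition."""
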