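"""Exception hierarchy shared across the toolkit."""


class EhrkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(EhrkitError):
    """A file or store does not conform to the expected layout."""


class ValidationError(EhrkitError):
    """An input violates a documented precondition or invariant."""


class StateError(EhrkitError):
    """An operation was called before its prerequisite state exists."""


class DegenerateInputError(EhrkitError):
    """The input is structurally valid but statistically degenerate."""


class IdentifiabilityError(EhrkitError):
    """No valid adjustment set exists for the requested causal query."""
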