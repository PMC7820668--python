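"""Exception hierarchy shared across the package."""


class MicrosearchError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MicrosearchError, ValueError):
    """A text input (profile TSV, Newick, metadata table) could not be parsed."""


class ValidationError(MicrosearchError, ValueError):
    """An input violates a documented precondition or invariant."""
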