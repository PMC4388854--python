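"""Exception hierarchy shared across the package."""


class PhylocanonError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PhylocanonError):
    """Malformed input text.

    ``token`` carries the offending token (or a short description of it) so
    callers can point at the exact place the input went wrong.
    """

    def __init__(self, message: str, token: str | None = None):
        self.token = token
        if token is not None:
            message = f"{message} (at {token!r})"
        super().__init__(message)


class MalformedSyntaxError(ParseError):
    """Input text does not follow the grammar."""


class NonPositiveLengthError(ParseError):
    """A branch length <= 0 was given; lengths must be strictly positive."""


class DuplicateLeafError(ParseError):
    """The same taxon label occurs on more than one leaf."""


class CyclicStructureError(ParseError):
    """Hybrid-node references induce a directed cycle."""


class CapExceededError(PhylocanonError):
    """An enumeration guard (switchings, paths, orderings) was exceeded.

    Enumeration is refused explicitly rather than silently truncated.
    """


class PreconditionError(PhylocanonError):
    """An operation was called on input violating its stated precondition."""
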