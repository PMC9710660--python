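"""Exception hierarchy for flexdot.

All errors raised on user input derive from :class:`FlexDotError` so callers
(and the CLI) can catch one base class.
"""


class FlexDotError(Exception):
    """Base class for all flexdot input/validation errors."""


class FormatError(FlexDotError):
    """Malformed input file or level string (wrong column count, bad separator)."""


class DuplicationError(FlexDotError):
    """The same (x, y) combination occurs more than once."""


class CapacityError(FlexDotError):
    """More display factors / levels than the available channels or symbols."""


class FactorLookupError(FlexDotError, KeyError):
    """A factor, gene, or cluster name is not present in the data."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return Exception.__str__(self)


class ValidationError(FlexDotError):
    """A precondition or invariant on parameters is violated."""


class ConsistencyError(FlexDotError):
    """Two objects that must agree (e.g. dendrogram leaves vs axis levels) differ."""
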