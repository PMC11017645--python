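"""Exception hierarchy for WLN processing.

Every error that points at the input carries ``position`` (0-based offset of
the offending character in the original string) so diagnostics can be rendered
as ``position: message``.  Ring errors point at the closing ``J`` of the
problematic ring block.
"""

from __future__ import annotations


class WLNError(Exception):
    """Base class for all WLN toolkit errors."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{position}: {message}"
        super().__init__(message)


class UnknownSymbol(WLNError):
    """A character outside the WLN character set."""


class MalformedLocant(WLNError):
    """A locant string that is empty or uses a letter beyond 'X'."""


class ParseError(WLNError):
    """Syntax or valence violation while building the WLN graph."""


class UnknownElement(ParseError):
    """A '-XX-' periodic code that names no element."""


class RingParseError(ParseError):
    """Error inside a ring block; position indexes the closing 'J'."""


class BadLocant(RingParseError):
    """A locant index beyond the ring system's locant path."""


class NoLocantPath(RingParseError):
    """The declared ring system admits no single locant path."""


class ValenceError(ParseError):
    """No legal bond-order / hydrogen assignment exists for an atom."""


class RecordError(WLNError):
    """A benchmark record that cannot be used (e.g. unparseable reference)."""
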