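"""wlnkit: Wiswesser Line Notation extraction, parsing and conversion."""

from .fsm import (MatcherConfig, MatchSpan, build_matcher, match_exact,
                  match_greedy, strip_annotation_suffix)
from .symbols import lookup_symbol, locant_to_index, index_to_locant

__all__ = [
    "MatcherConfig",
    "MatchSpan",
    "build_matcher",
    "match_exact",
    "match_greedy",
    "strip_annotation_suffix",
    "lookup_symbol",
    "locant_to_index",
    "index_to_locant",
    "parse",
    "convert",
]
__version__ = "0.1.0"


def parse(wln: str, **options):
    """Parse a WLN string into a :class:`~wlnkit.parser.WLNGraph`."""
    from .parser import parse as _parse

    return _parse(wln, **options)


def convert(wln: str, **options) -> str:
    """Convert a WLN string to canonical SMILES (or InChI)."""
    from .assemble import convert as _convert

    return _convert(wln, **options)
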