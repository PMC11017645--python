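"""The WLN character set and per-symbol semantics.

WLN is written over the upper-case letters A-Z, the digits 0-9 and four
punctuation marks (``&``, ``-``, ``/`` and the space).  Each letter carries a
fixed acyclic meaning -- an element, a condensed functional group, or a piece
of ring punctuation -- together with an allowed *branch count* (the "WLN
degree": the number of children a symbol may take in the parse tree, not a
bond-order sum).  This module is the single source of truth for those
semantics; the matcher, the parser and the assembler all consult it.

Locants (ring-position letters) are also handled here: a locant is one letter
``A``-``X``; positions past ``X`` are written by appending ``&`` characters,
each of which advances the index by a further 24 (the size of the A-X range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import MalformedLocant, UnknownSymbol

Category = Literal[
    "atom",          # acyclic element / functional-group symbol
    "digit",         # alkyl chain length (or ring size inside a ring block)
    "ring_open",     # L, T, D
    "ring_close",    # J
    "locant_only",   # A
    "unsaturator",   # U
    "modifier",      # W: adds two double-bonded oxygens to its neighbour
    "punctuation",   # &, -, /, space
]

ImpliedFill = Literal["hydrogen", "methyl"]


@dataclass(frozen=True)
class SymbolSpec:
    """Semantics of one WLN character (one row of the symbol table)."""

    char: str
    meaning: str
    category: Category
    element: str | None = None       # atomic symbol when the char denotes an atom
    max_branches: int = 0            # allowed branch count ("WLN degree")
    exact_branches: bool = False     # C: full-valence carbon, 4 exactly
    expandable: bool = False         # R: benzene, substituents expand it
    terminating: bool = False
    locant_capable: bool = False     # letters A..X can serve as ring locants
    implied_charge: int = 0
    implied_fill: ImpliedFill = "hydrogen"  # X, Y, K fill unused slots with methyl
    must_unsaturate: bool = False    # C carries an implied double/triple bond
    implied_hydrogens: int = 0       # condensed groups: Q=OH, Z=NH2, M=NH


def _letters_spec() -> dict[str, SymbolSpec]:
    mk = SymbolSpec
    loc = lambda c: c <= "X"  # noqa: E731  - "any letter character up to X"
    table = {
        "A": mk("A", "Locant only", "locant_only", locant_capable=True),
        "B": mk("B", "Boron", "atom", element="B", max_branches=3, locant_capable=True),
        "C": mk("C", "Carbon (full valence, implied unsaturation)", "atom", element="C",
                max_branches=4, exact_branches=True, must_unsaturate=True,
                locant_capable=True),
        "D": mk("D", "Open chelate", "ring_open", locant_capable=True),
        "E": mk("E", "Bromine", "atom", element="Br", max_branches=1,
                terminating=True, locant_capable=True),
        "F": mk("F", "Fluorine", "atom", element="F", max_branches=1,
                terminating=True, locant_capable=True),
        "G": mk("G", "Chlorine", "atom", element="Cl", max_branches=1,
                terminating=True, locant_capable=True),
        "H": mk("H", "Hydrogen", "atom", element="H", max_branches=1,
                terminating=True, locant_capable=True),
        "I": mk("I", "Iodine", "atom", element="I", max_branches=1,
                terminating=True, locant_capable=True),
        "J": mk("J", "Ring closure", "ring_close", terminating=True,
                locant_capable=True),
        "K": mk("K", "Nitrogen (1+ charge, 4 implied methyls)", "atom", element="N",
                max_branches=4, implied_charge=1, implied_fill="methyl",
                locant_capable=True),
        "L": mk("L", "Open carbocycle", "ring_open", locant_capable=True),
        "M": mk("M", "Secondary amine (NH)", "atom", element="N", max_branches=2,
                implied_hydrogens=1, locant_capable=True),
        "N": mk("N", "Nitrogen", "atom", element="N", max_branches=3,
                locant_capable=True),
        "O": mk("O", "Oxygen", "atom", element="O", max_branches=2,
                locant_capable=True),
        "P": mk("P", "Phosphorus", "atom", element="P", max_branches=3,
                locant_capable=True),
        "Q": mk("Q", "Hydroxyl (OH)", "atom", element="O", max_branches=1,
                terminating=True, implied_hydrogens=1, locant_capable=True),
        "R": mk("R", "Benzene", "atom", element="C", max_branches=1,
                expandable=True, locant_capable=True),
        "S": mk("S", "Sulphur", "atom", element="S", max_branches=3,
                locant_capable=True),
        "T": mk("T", "Open heterocycle", "ring_open", locant_capable=True),
        "U": mk("U", "Unsaturate bond", "unsaturator", locant_capable=True),
        "V": mk("V", "Carbonyl (C=O)", "atom", element="C", max_branches=2,
                locant_capable=True),
        "W": mk("W", "Add -oxylate (two =O on the neighbour)", "modifier",
                locant_capable=True),
        "X": mk("X", "Carbon (4 implied methyls)", "atom", element="C",
                max_branches=4, implied_fill="methyl", locant_capable=True),
        "Y": mk("Y", "Carbon (3 implied methyls)", "atom", element="C",
                max_branches=3, implied_fill="methyl"),
        "Z": mk("Z", "Primary amine (NH2)", "atom", element="N",
                implied_hydrogens=2, terminating=True),
    }
    for c, spec in table.items():
        assert spec.locant_capable == loc(c), c
    return table


def _build_table() -> dict[str, SymbolSpec]:
    table = _letters_spec()
    for d in "0123456789":
        table[d] = SymbolSpec(d, "Alkane chain of length n", "digit")
    table["&"] = SymbolSpec("&", "Branch/ring pop; ion separator; aromatic flag",
                            "punctuation")
    table["-"] = SymbolSpec("-", "Element code / wide ring size / ring chain",
                            "punctuation")
    table["/"] = SymbolSpec("/", "Crossed bond clause", "punctuation")
    table[" "] = SymbolSpec(" ", "Separator (locants, ions, ring clauses)",
                            "punctuation")
    return table


SYMBOL_TABLE: dict[str, SymbolSpec] = _build_table()

#: Characters that make up the WLN language.
WLN_CHARSET = frozenset(SYMBOL_TABLE)

#: Letters with an acyclic atom meaning (includes the benzene shorthand R).
ATOM_SYMBOLS = frozenset(c for c, s in SYMBOL_TABLE.items() if s.category == "atom")

#: Valence-1 symbols and saturated groups that close the current branch.
TERMINATORS = frozenset(
    c for c, s in SYMBOL_TABLE.items() if s.terminating and s.category == "atom"
)

#: Ring-block openers.
RING_OPENERS = frozenset("LTD")

#: Symbols that open a branch (can host more than one child).
BRANCHERS = frozenset(
    c for c, s in SYMBOL_TABLE.items()
    if s.category == "atom" and s.max_branches >= 3
)


def lookup_symbol(c: str, position: int | None = None) -> SymbolSpec:
    """Return the :class:`SymbolSpec` for character ``c``.

    Pure and total over the WLN character set; anything else raises
    :class:`~wlnkit.errors.UnknownSymbol`.
    """
    try:
        return SYMBOL_TABLE[c]
    except KeyError:
        raise UnknownSymbol(f"character {c!r} is not part of the WLN character set",
                            position) from None


def locant_to_index(s: str) -> int:
    """Index of a locant string: one letter A-X plus optional trailing '&'s.

    ``A`` -> 1 ... ``X`` -> 24; each trailing ``&`` adds a further 24, so
    ``A&`` -> 25, ``B&&`` -> 50.
    """
    if not s:
        raise MalformedLocant("empty locant")
    letter, ext = s[0], s[1:]
    if not ("A" <= letter <= "X"):
        raise MalformedLocant(f"locant letter {letter!r} is beyond 'X'")
    if ext.strip("&"):
        raise MalformedLocant(f"locant extension {ext!r} may only contain '&'")
    return (ord(letter) - ord("A") + 1) + 24 * len(ext)


def index_to_locant(i: int) -> str:
    """Inverse of :func:`locant_to_index` (round-trips for all i >= 1)."""
    if i < 1:
        raise MalformedLocant(f"locant index must be positive, got {i}")
    ext, rank = divmod(i - 1, 24)
    return chr(ord("A") + rank) + "&" * ext


def symbol_table_rows() -> list[tuple[str, str, str, str, str]]:
    """Machine-readable dump of the symbol table, one row per character.

    Columns: char, meaning, allowed branches, terminating, locant-capable.
    Exported so the table can be diffed against an independent transcription.
    """
    rows = []
    for c in sorted(SYMBOL_TABLE):
        s = SYMBOL_TABLE[c]
        branches = str(s.max_branches)
        if s.exact_branches:
            branches += " exactly"
        if s.expandable:
            branches += " (expandable)"
        rows.append((
            "space" if c == " " else c,
            s.meaning,
            branches if s.category not in ("punctuation",) else "",
            "yes" if s.terminating else "no",
            "yes" if s.locant_capable else "no",
        ))
    return rows
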