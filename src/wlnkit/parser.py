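"""Character-by-character construction of the WLN graph.

Acyclic WLN builds a tree: each symbol is an atom or condensed group, digits
append alkyl chains, terminator symbols close the current branch and return
to the last open branching symbol, ``&`` pops a branching level explicitly,
``U`` raises the order of the next bond, a space-ampersand starts a new ion
component, and ``-XX-`` embeds a two-letter periodic code.  Ring blocks are
located first and spliced out to the :mod:`~wlnkit.rings` routines; once a
block closes, space-separated locant clauses attach substituents to the ring
and dash clauses chain, spiro-fuse or (for macrocycles) close rings.

Recoverable faults -- an over-branched symbol with a higher-degree
counterpart of the same element (``M`` -> ``N``, ``Q`` -> ``O``) and spaces
that make no semantic sense (a typical OCR artefact) -- are repaired and
logged by default; ``strict=True`` turns every fault into a
:class:`~wlnkit.errors.ParseError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParseError, RingParseError, UnknownElement, UnknownSymbol
from .symbols import (ATOM_SYMBOLS, RING_OPENERS, SYMBOL_TABLE,
                      locant_to_index, lookup_symbol)

#: WLN degree ladder for run-time symbol raising (same element, more branches)
RAISE_LADDER = {"M": "N", "Q": "O"}

_PERIODIC = None


def _periodic():
    global _PERIODIC
    if _PERIODIC is None:
        from rdkit import Chem

        _PERIODIC = Chem.GetPeriodicTable()
    return _PERIODIC


@dataclass
class WLNNode:
    """One symbol of the WLN graph (an atom after shorthand expansion)."""

    id: int
    source_char: str
    source_position: int
    element: str | None
    max_conn: int                 # the WLN degree: allowed branch count
    formal_charge: int = 0
    min_hydrogens: int = 0        # hydrogens the symbol itself guarantees
    fill_methyl: bool = False     # X, Y, K fill unused slots with methyl
    must_unsaturate: bool = False  # C: full-valence carbon, implied unsat
    is_ring_member: bool = False
    aromatic: bool = False
    ring_carbonyl: bool = False   # in-ring V: carries an exocyclic =O
    never_aromatic: bool = False  # in-ring X: explicitly saturated carbon
    closed: bool = False          # popped with '&': accepts no more children


@dataclass
class WLNGraph:
    """Directed component graph of WLN symbols with bond orders."""

    nodes: list[WLNNode] = field(default_factory=list)
    edges: list[list[int]] = field(default_factory=list)  # [a, b, order]
    components: list[int] = field(default_factory=list)   # root node ids
    ring_blocks: list[tuple[int, int]] = field(default_factory=list)
    ring_systems: list = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def new_node(self, element: str | None, source_char: str,
                 source_position: int, max_conn: int, **kw) -> WLNNode:
        node = WLNNode(len(self.nodes), source_char, source_position,
                       element, max_conn, **kw)
        self.nodes.append(node)
        return node

    def add_edge(self, a: int, b: int, order: int = 1) -> None:
        if a == b:
            raise ParseError("self-bond in WLN graph")
        self.edges.append([a, b, order])

    def set_order(self, a: int, b: int, order: int) -> None:
        for e in self.edges:
            if {e[0], e[1]} == {a, b}:
                e[2] = order
                return
        self.add_edge(a, b, order)

    def neighbours(self, node_id: int) -> list[tuple[int, int]]:
        out = []
        for a, b, o in self.edges:
            if a == node_id:
                out.append((b, o))
            elif b == node_id:
                out.append((a, o))
        return out

    def degree(self, node_id: int) -> int:
        return len(self.neighbours(node_id))

    def bond_order_sum(self, node_id: int) -> int:
        return sum(o for _, o in self.neighbours(node_id))


# ---------------------------------------------------------------------------

@dataclass
class _Macro:
    opener: str
    system: object          # the embedded RingSystem


class _Parser:
    def __init__(self, wln: str, recover: bool = True):
        self.wln = wln
        self.recover = recover
        self.g = WLNGraph()
        self.i = 0
        # chain state
        self.attach: WLNNode | None = None
        self.pending_u = 0
        self.u_position = -1
        self.stack: list[WLNNode] = []          # open branching symbols
        self.children: dict[int, int] = {}      # children taken per node
        self.done = False                       # chain closed, no branch open
        self.component_open = False
        # ring state
        self.cur_ring = None
        self.ring_stack: list = []
        self.macro: _Macro | None = None

    # -- small helpers ------------------------------------------------------
    def err(self, msg: str, pos: int | None = None):
        raise ParseError(msg, self.i if pos is None else pos)

    def warn(self, msg: str, pos: int) -> None:
        self.g.warnings.append(f"{pos}: {msg}")

    def _capacity(self, node: WLNNode) -> int:
        return node.max_conn - self.g.degree(node.id)

    def _pop_exhausted(self) -> None:
        while self.stack and (self._capacity(self.stack[-1]) < 1
                              or self.stack[-1].closed):
            self.stack.pop()

    def _return_to_branch(self) -> None:
        """A branch terminated: continue from the last open branching symbol."""
        self._pop_exhausted()
        if self.stack:
            self.attach = self.stack[-1]
        else:
            self.attach = None
            self.done = True

    def _raise_on_pop(self, pos: int) -> bool:
        """A '&' pop with no open branch: look for a symbol that becomes a
        legal branching point once raised (the common over-branched 'M')."""
        node = self.attach
        seen: set[int] = set()
        while node is not None and node.id not in seen:
            seen.add(node.id)
            if node.source_char in RAISE_LADDER:
                if not self._raise_symbol(node, pos):
                    return False
                self.attach = node
                self.done = False
                return True
            parents = [a for a, _ in self.g.neighbours(node.id)
                       if a < node.id]
            node = self.g.nodes[parents[-1]] if parents else None
        return False

    def _raise_symbol(self, node: WLNNode, pos: int) -> bool:
        target = RAISE_LADDER.get(node.source_char)
        if target is None:
            return False
        spec = SYMBOL_TABLE[target]
        self.warn(f"raised over-branched '{node.source_char}' to "
                  f"'{target}'", node.source_position)
        node.source_char = target
        node.max_conn = spec.max_branches
        node.min_hydrogens = spec.implied_hydrogens
        return True

    def _bond(self, parent: WLNNode, child: WLNNode, pos: int) -> None:
        order = 1 + self.pending_u
        self.pending_u = 0
        while self._capacity(parent) < 1 or parent.closed:
            if parent.closed or not (self.recover
                                     and self._raise_symbol(parent, pos)):
                self.err(
                    f"symbol '{parent.source_char}' at position "
                    f"{parent.source_position} cannot take another branch",
                    pos)
        self.g.add_edge(parent.id, child.id, order)

    def _new_atom(self, element: str, char: str, pos: int, max_conn: int,
                  **kw) -> WLNNode:
        if self.done and self.attach is None:
            self.err(f"symbol {char!r} follows a terminated chain", pos)
        node = self.g.new_node(element, char, pos, max_conn, **kw)
        if self.attach is not None:
            self._bond(self.attach, node, pos)
        else:
            self.g.components.append(node.id)
            self.component_open = True
        return node

    def _start_component(self) -> None:
        self.attach = None
        self.pending_u = 0
        self.stack = []
        self.done = False
        self.cur_ring = None
        self.ring_stack = []
        self.macro = None
        self.component_open = False

    # -- main loop ----------------------------------------------------------
    def parse(self) -> WLNGraph:
        wln = self.wln
        if not wln or not wln.strip():
            raise ParseError("empty WLN string", 0)
        n = len(wln)
        while self.i < n:
            c = wln[self.i]
            if c == " ":
                self._space()
            elif c.isdigit():
                self._digits()
            elif c in RING_OPENERS:
                self._ring_block()
            elif c == "-":
                self._dash()
            elif c == "&":
                self._ampersand()
            elif c == "U":
                self._unsaturate()
            elif c in ATOM_SYMBOLS or c == "W":
                self._atom(c)
            elif c in ("A", "J", "/"):
                self.err(f"{c!r} has no meaning outside a ring block")
            elif c.islower():
                self.err(f"lower-case character {c!r} was never part of WLN")
            else:
                raise UnknownSymbol(
                    f"character {c!r} is not part of the WLN character set",
                    self.i)
        if self.pending_u:
            raise ParseError("unsaturation 'U' lacks a following atom",
                             self.u_position)
        return self.g

    # -- chain symbols ------------------------------------------------------
    def _atom(self, c: str) -> None:
        spec = lookup_symbol(c, self.i)
        pos = self.i
        self.i += 1
        if c == "R":
            self._benzene(pos)
            return
        node = self._new_atom(spec.element, c, pos,
                              max_conn=max(1, spec.max_branches),
                              formal_charge=spec.implied_charge,
                              min_hydrogens=spec.implied_hydrogens,
                              fill_methyl=spec.implied_fill == "methyl",
                              must_unsaturate=spec.must_unsaturate)
        if c == "W":
            # dioxo modifier: expanded onto its neighbour later; it closes
            # the branch the way a terminator does
            node.max_conn = 1
            if self.g.degree(node.id) > 0:
                self._return_to_branch()
            else:
                self.attach = node
            return
        if spec.terminating and self.g.degree(node.id) > 0:
            self._return_to_branch()
        else:
            self.attach = node
            if spec.max_branches >= 3:
                self.stack.append(node)

    def _benzene(self, pos: int) -> None:
        from .rings import build_benzene

        if self.done and self.attach is None:
            self.err("'R' follows a terminated chain", pos)
        system = build_benzene(self.g, pos)
        root = system.node_at(1)
        if self.attach is not None:
            self._bond(self.attach, root, pos)
        else:
            self.g.components.append(root.id)
        if self.cur_ring is not None:
            self.ring_stack.append(self.cur_ring)
        self.cur_ring = system
        self.g.ring_systems.append(system)
        # R is terminating for the chain; substituents use locant clauses
        self._return_to_branch()
        self.attach = root
        self.done = False

    def _digits(self) -> None:
        start = self.i
        while self.i < len(self.wln) and self.wln[self.i].isdigit():
            self.i += 1
        count = int(self.wln[start:self.i])
        if count == 0:
            self.err("'0' denotes a zero-length alkyl chain", start)
        for k in range(count):
            node = self._new_atom("C", self.wln[start], start + min(
                k, self.i - start - 1), max_conn=4)
            self.attach = node

    def _unsaturate(self) -> None:
        if self.attach is None:
            self.err("'U' needs a parent atom")
        if self.attach.must_unsaturate:
            self.err("explicit 'U' after 'C' is redundant and disallowed")
        self.pending_u += 1
        self.u_position = self.i
        if self.pending_u > 2:
            self.err("at most two 'U' in a row (triple bond)")
        self.i += 1

    def _ampersand(self) -> None:
        # plain '&' after an atom: close the current branching level
        pos = self.i
        self.i += 1
        self._pop_exhausted()
        if self.stack:
            node = self.stack.pop()
            node.closed = True
            self._pop_exhausted()
            self.attach = self.stack[-1] if self.stack else None
            if self.attach is None:
                self.done = True
        elif self.recover and self._raise_on_pop(pos):
            pass
        elif self.ring_stack:
            # pop back to an earlier ring system
            self.cur_ring = self.ring_stack.pop()
            self.attach = None
        elif self.cur_ring is not None:
            self.attach = None
        else:
            self.err("'&' pops an empty branch stack", pos)

    # -- element codes and dash clauses -------------------------------------
    def _dash(self) -> None:
        wln, pos = self.wln, self.i
        j = pos + 1
        while j < len(wln) and wln[j].isalpha() and wln[j].isupper():
            j += 1
        if j < len(wln) and wln[j] == "-" and j - pos - 1 in (1, 2):
            code = wln[pos + 1:j]
            self._element_code(code, pos)
            self.i = j + 1
            return
        if j == pos + 1 and pos + 1 < len(wln) and wln[pos + 1] == " ":
            self._dash_clause(pos)
            return
        self.err("'-' must introduce an element code or a ring clause", pos)

    def _element_code(self, code: str, pos: int) -> None:
        pt = _periodic()
        symbol = code.capitalize()
        if symbol not in _valid_symbols(pt):
            raise UnknownElement(f"unknown element code -{code}-", pos)
        valence = pt.GetDefaultValence(symbol)
        if valence < 1:
            valence = 6           # metals and flexible-valence elements
        node = self._new_atom(symbol, code, pos, max_conn=valence)
        self.attach = node
        if node.max_conn >= 3:
            self.stack.append(node)

    def _dash_clause(self, pos: int) -> None:
        """``- <locant>...``: chained ring, or the macrocycle return clause."""
        wln = self.wln
        k = pos + 2
        if k >= len(wln) or not ("A" <= wln[k] <= "X"):
            self.err("expected a locant after '- '", k)
        loc, k = _read_locant_str(wln, k)
        if k < len(wln) and wln[k].isdigit():
            # macro return: bond back to the locant, ring size declared
            j = k
            while j < len(wln) and wln[j].isdigit():
                j += 1
            if j >= len(wln) or wln[j] != "J":
                self.err("macrocycle return clause must end with J", j)
            if self.macro is None:
                self.err("macrocycle return clause without a macro opener",
                         pos)
            if self.cur_ring is None:
                self.err("no ring system for the macrocycle return", pos)
            target = self.cur_ring.node_at(loc, pos)
            src = self.attach
            if src is None:
                self.err("macrocycle return needs an attachment branch", pos)
            order = 1 + self.pending_u
            self.pending_u = 0
            self.g.add_edge(src.id, target.id, order)
            self.macro = None
            self.done = False
            self.attach = None
            self.i = j + 1
            return
        if k < len(wln) and wln[k] in RING_OPENERS:
            src = self.attach
            self.i = k
            system = self._ring_block(attach_override=loc, attach_from=src)
            return
        self.err("expected a ring block or macro size after '- <locant>'", k)

    # -- spaces --------------------------------------------------------------
    def _space(self) -> None:
        wln, pos = self.wln, self.i
        j = pos + 1
        if j >= len(wln):
            if self.recover:
                self.warn("trailing space ignored", pos)
                self.i = j
                return
            self.err("trailing space", pos)
        nxt = wln[j]
        if nxt == "&":
            if j + 1 < len(wln) and wln[j + 1] == "-":
                # " &- ...": close the branch, then the macro/spiro clause
                self.i = j + 1
                self._pop_branch_for_clause()
                self._dash()
                return
            if j + 1 < len(wln) and wln[j + 1] == "&":
                self.err("'&&' introduces an annotation suffix, not WLN "
                         "notation; strip it before parsing", j)
            # new ion component
            self.i = j + 1
            self._start_component()
            return
        if "A" <= nxt <= "X" and self.cur_ring is not None:
            loc, k = _read_locant_str(wln, j)
            if k > j + 1 and k < len(wln) and wln[k] == "-":
                # spiro: the locant branch character is replaced by '&' and
                # the chained ring shares this atom
                loc, _ = _read_locant_str(wln, j, stop_before_dash=True)
                self._spiro(loc, k)
                return
            node = self.cur_ring.node_at(loc, j)
            self.attach = node
            self.done = False
            self.i = k
            return
        # a space that makes no semantic sense (OCR fault): skip it
        if self.recover:
            self.warn("skipped a space that makes no semantic sense", pos)
            self.i = j
            return
        self.err("unexpected space", pos)

    def _spiro(self, shared_loc: int, dash_at: int) -> None:
        """Spiro fusion: one atom shared between the old and the new ring."""
        wln = self.wln
        old = self.cur_ring.node_at(shared_loc, dash_at)
        k = dash_at + 1
        if k >= len(wln) or wln[k] != " ":
            self.err("expected '- <locant>' in a spiro clause", k)
        loc2, k = _read_locant_str(wln, k + 1)
        if k >= len(wln) or wln[k] not in RING_OPENERS:
            self.err("spiro clause must introduce a ring block", k)
        self.i = k
        system = self._ring_block(attach_override=None, attach_from=None,
                                  no_component=True)
        new = system.node_at(loc2, dash_at)
        for e in self.g.edges:
            if e[0] == new.id:
                e[0] = old.id
            if e[1] == new.id:
                e[1] = old.id
        new.element = None
        new.is_ring_member = False
        system.nodes[loc2 - 1] = old

    def _pop_branch_for_clause(self) -> None:
        self._pop_exhausted()
        if self.stack:
            node = self.stack.pop()
            self.attach = node
            node.closed = False

    # -- ring blocks ---------------------------------------------------------
    def _ring_block(self, attach_override: int | None = None,
                    attach_from: WLNNode | None = None,
                    no_component: bool = False):
        from .rings import build_ring_system, parse_ring_block

        wln, pos = self.wln, self.i
        if self.done and self.attach is None and attach_from is None \
                and attach_override is None:
            self.err("ring block follows a terminated chain", pos)
        start = pos
        macro_opener = None
        if pos + 2 < len(wln) and wln[pos + 1] == "-" \
                and wln[pos + 2] in RING_OPENERS:
            macro_opener = wln[pos]
            start = pos + 2
        end = _find_block_end(wln, start)
        if end is None:
            raise RingParseError("ring block has no closing J", pos)
        block = parse_ring_block(wln[start:end + 1], start)
        system = build_ring_system(self.g, block)
        self.g.ring_blocks.append((pos, end))
        # attach the ring into the surrounding chain
        attach_at = attach_override or 1
        root = system.node_at(attach_at, pos)
        src = attach_from if attach_from is not None else self.attach
        if src is not None and not no_component:
            self._bond(src, root, pos)
        elif not no_component:
            self.g.components.append(root.id)
            self.pending_u = 0
        if self.cur_ring is not None:
            self.ring_stack.append(self.cur_ring)
        self.cur_ring = system
        self.g.ring_systems.append(system)
        if macro_opener is not None:
            self.macro = _Macro(macro_opener, system)
        self.attach = None
        self.done = False
        self.i = end + 1
        return system


def _valid_symbols(pt) -> set[str]:
    out = set()
    for z in range(1, 119):
        try:
            out.add(pt.GetElementSymbol(z))
        except Exception:  # pragma: no cover
            break
    return out


def _read_locant_str(s: str, at: int,
                     stop_before_dash: bool = False) -> tuple[int, int]:
    j = at + 1
    while j < len(s) and s[j] == "&":
        j += 1
    if stop_before_dash and j < len(s) and s[j] == "-" and s[j - 1] == "&":
        j -= 1                 # the final '&' is a spiro marker, not an index
    return locant_to_index(s[at:j]), j


def _find_block_end(wln: str, start: int) -> int | None:
    """Index of the ``J`` closing the block opened at ``start``.

    ``J`` preceded by a space is a locant; ``-XX-`` element codes are
    skipped; an embedded ``-<opener><digit>`` opens a nested (macro) block.
    """
    depth = 1
    i = start + 1
    n = len(wln)
    while i < n:
        c = wln[i]
        if c == "-" and i + 2 < n and wln[i + 1].isalpha() \
                and wln[i + 2] in "-0123456789" :
            if wln[i + 1] in RING_OPENERS and wln[i + 2].isdigit():
                depth += 1
                i += 2
                continue
            if wln[i + 2] == "-":
                i += 3
                continue
        if c == "-" and i + 3 < n and wln[i + 1].isalpha() \
                and wln[i + 2].isalpha() and wln[i + 3] == "-":
            i += 4
            continue
        if c == "J" and wln[i - 1] != " ":
            depth -= 1
            if depth == 0:
                return i
        i += 1
    return None


# ---------------------------------------------------------------------------

def parse(wln: str, recover: bool = True) -> WLNGraph:
    """Parse a WLN string into its symbol graph.

    ``recover=False`` (strict mode) turns run-time repairs -- symbol raising
    and OCR-space skipping -- into :class:`~wlnkit.errors.ParseError`.
    """
    return _Parser(wln, recover=recover).parse()
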