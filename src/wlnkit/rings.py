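"""Cyclic WLN: ring-block parsing, locant paths and ring-system assembly.

A ring block runs from an opener (``L`` carbocycle, ``T`` heterocycle, ``D``
chelate) to the closing ``J`` and declares, in order: the sub-ring sizes
(each with an optional *lowest locant*, default ``A``), an optional
multicyclic clause (the number and locants of atoms shared by more than two
sub-rings, followed by the size of the whole system as a locant), heteroatom
placements, explicit ring unsaturations, bridge locants, and per-sub-ring
aromaticity flags (``&`` aromatic / ``T`` aliphatic; a single flag applies to
the whole system, and no flag at all means aromatic).

Ring atoms are numbered ``A``, ``B``, ``C`` ... along the *locant path* -- a
single path visiting every ring atom once (a Hamiltonian path over the ring
system) whose start is the atom shared by the most sub-rings.  Assembly works
the way the notation reads: sub-rings are closed left to right, each one
being a cycle of its declared size whose lowest locant is the declared one;
new atoms are appended to the end of the path as needed, and each sub-ring
contributes one new (closure) bond.  Where several geometries satisfy the
declaration, the candidate minimising the locant sum (the summed locant
values shared between pairs of sub-cycles) is chosen; this reproduces the
published numbering of fused, perifused and multicyclic systems.  Bridged
systems place their bridge atoms off the path, bonded to the declared bridge
locant; these carry the highest locants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

from .errors import BadLocant, NoLocantPath, RingParseError
from .symbols import locant_to_index

#: letters with an in-ring heteroatom meaning
_ELEMENT_LETTERS = frozenset("BCKMNOPSVXY")

_RING_ELEMENT = {
    "B": ("B", 0, 0), "C": ("C", 0, 0), "K": ("N", 1, 0), "M": ("N", 0, 1),
    "N": ("N", 0, 0), "O": ("O", 0, 0), "P": ("P", 0, 0), "S": ("S", 0, 0),
    "V": ("C", 0, 0), "X": ("C", 0, 0), "Y": ("C", 0, 0),
}  # char -> (element, formal charge, forced hydrogens)


@dataclass
class RingEntry:
    """One declared sub-ring: its lowest locant (1-based index) and size."""

    locant: int
    size: int
    explicit_locant: bool = False


@dataclass
class RingBlock:
    """Parsed contents of one ``L|T|D ... J`` ring block."""

    opener: str
    text: str
    j_position: int
    entries: list[RingEntry] = field(default_factory=list)
    multicyclic_points: list[int] = field(default_factory=list)
    system_size: int | None = None
    hetero: list[tuple[int, str]] = field(default_factory=list)   # (locant, char)
    unsats: list[tuple[int, int | None]] = field(default_factory=list)
    bridges: list[int] = field(default_factory=list)
    crossed: list[tuple[int, int]] = field(default_factory=list)  # extra bonds
    flags: list[bool] = field(default_factory=list)               # per sub-ring

    @property
    def n_atoms(self) -> int:
        if self.system_size is not None:
            return self.system_size
        total = sum(e.size for e in self.entries)
        return total - 2 * (len(self.entries) - 1) - len(self.bridges)

    def ring_aromatic(self) -> list[bool]:
        r = len(self.entries)
        if not self.flags:
            return [True] * r           # no flag: aromatic by default
        if len(self.flags) == 1:
            return [self.flags[0]] * r  # one flag covers the whole system
        if len(self.flags) != r:
            raise RingParseError(
                f"{len(self.flags)} aromaticity flags for {r} sub-rings",
                self.j_position)
        return list(self.flags)


# ---------------------------------------------------------------------------
# Block text -> RingBlock
# ---------------------------------------------------------------------------

_SIZES_RE = re.compile(r"^([A-X]&*)?((?:[0-9]|-[0-9]{2,}-)+)")
_MULTI_RE = re.compile(r"^([0-9]+)((?:[A-X]&*)+)$")
_LOCANT_RE = re.compile(r"^([A-X])(&*)")


def _read_locant(s: str, at: int, jpos: int | None = None) -> tuple[int, int]:
    m = _LOCANT_RE.match(s[at:])
    if not m:
        raise RingParseError(f"expected a locant at {s[at:at + 3]!r}", jpos)
    return locant_to_index(m.group(0)), at + m.end()


def _is_multi_clause(tok: str, nxt_tok: str | None) -> bool:
    m = _MULTI_RE.match(tok)
    if not m:
        return False
    locs = re.findall(r"[A-X]&*", m.group(2))
    return (len(locs) == int(m.group(1)) and nxt_tok is not None
            and re.fullmatch(r"[A-X]&*", nxt_tok) is not None)


def parse_ring_block(text: str, offset: int = 0) -> RingBlock:
    """Parse the text of one ring block (opener through closing ``J``)."""
    if not text or text[0] not in "LTD":
        raise RingParseError("ring block must open with L, T or D", offset)
    jpos = offset + len(text) - 1
    if text[-1] != "J":
        raise RingParseError("ring block must close with J", jpos)
    block = RingBlock(opener=text[0], text=text, j_position=jpos)
    tokens = text[1:-1].lstrip(" ").split(" ")
    if any(t == "" for t in tokens):
        raise RingParseError("empty clause (double space) in ring block", jpos)

    # --- phase 1: sub-ring sizes -----------------------------------------
    ti = 0
    rest = ""
    while ti < len(tokens):
        tok = tokens[ti]
        if _is_multi_clause(tok, tokens[ti + 1] if ti + 1 < len(tokens) else None):
            break
        m = _SIZES_RE.match(tok)
        if not m:
            break
        sizes = [int(a or b) for a, b in
                 re.findall(r"-([0-9]{2,})-|([0-9])", m.group(2))]
        if any(s < 3 for s in sizes):
            break
        loc = locant_to_index(m.group(1)) if m.group(1) else 1
        for k, s in enumerate(sizes):
            block.entries.append(
                RingEntry(loc if k == 0 else 1, s,
                          explicit_locant=bool(m.group(1)) and k == 0))
        ti += 1
        if m.end() < len(tok):
            rest = tok[m.end():]
            break
    if not block.entries:
        raise RingParseError("ring block declares no sub-ring sizes", jpos)

    # --- phase 2: multicyclic clause + system size ------------------------
    if not rest and ti < len(tokens) and _is_multi_clause(
            tokens[ti], tokens[ti + 1] if ti + 1 < len(tokens) else None):
        m = _MULTI_RE.match(tokens[ti])
        locs = re.findall(r"[A-X]&*", m.group(2))
        block.multicyclic_points = [locant_to_index(x) for x in locs]
        block.system_size = locant_to_index(tokens[ti + 1])
        ti += 2

    n_est = block.n_atoms

    # --- phase 3: heteroatoms, unsaturations, bridges, flags --------------
    pointer = 1        # implied heteroatom position: after the last locant seen
    anchor = 1         # position an unsaturation clause refers to
    in_flags = False
    pending_partner = False

    def classify(tok: str, j: int) -> str:
        c = tok[j]
        nxt = tok[j + 1] if j + 1 < len(tok) else None
        if in_flags:
            return "flag" if c in "&T" else "bad"
        if c == "&":
            return "flag"
        if "A" <= c <= "X" and locant_to_index(c) <= n_est:
            if nxt == "U":
                return "locant"
            if (nxt in _ELEMENT_LETTERS
                    and (j + 2 >= len(tok) or tok[j + 2] in "&T-")
                    and not (c in _ELEMENT_LETTERS and j + 2 < len(tok))):
                return "locant"
        if c in _ELEMENT_LETTERS:
            return "element"
        if c == "T":
            return "flag"
        if "A" <= c <= "X":
            return "bridge"
        return "bad"

    while rest or ti < len(tokens):
        if rest:
            tok = rest
            rest = ""
        else:
            tok = tokens[ti]
            ti += 1
        j = 0
        if pending_partner:
            partner, j = _read_locant(tok, 0, jpos)
            loc, _ = block.unsats[-1]
            block.unsats[-1] = (loc, partner)
            pending_partner = False
        while j < len(tok):
            c = tok[j]
            if c == "/":
                if j + 2 >= len(tok):
                    raise RingParseError("incomplete crossed-bond clause", jpos)
                a, j2 = _read_locant(tok, j + 1, jpos)
                b, j = _read_locant(tok, j2, jpos)
                block.crossed.append((a, b))
                continue
            if c.isdigit():
                if j + 1 < len(tok) and tok[j + 1] == "/":
                    j += 1      # crossed-bond clauses carry the ring size
                    continue
                raise RingParseError(
                    f"unexpected digit {c!r} in ring clause", jpos)
            if c == "U":
                block.unsats.append((anchor, None))
                j += 1
                if j < len(tok) and tok[j] == "-":
                    pending_partner = True   # explicit partner: "HU- M"
                    j += 1
                continue
            kind = classify(tok, j)
            if kind == "flag":
                in_flags = True
                block.flags.append(c == "&")
                j += 1
            elif kind == "locant":
                pointer, j = _read_locant(tok, j, jpos)
                anchor = pointer
            elif kind == "element":
                block.hetero.append((pointer, c))
                anchor = pointer
                pointer += 1
                j += 1
            elif kind == "bridge":
                block.bridges.append(locant_to_index(c))
                pointer = block.bridges[-1] + 1
                anchor = block.bridges[-1]
                j += 1
            else:
                raise RingParseError(
                    f"unexpected character {c!r} in ring clause", jpos)

    for loc, _ in block.hetero:
        if loc > block.n_atoms:
            raise BadLocant(
                f"heteroatom locant index {loc} exceeds ring system size "
                f"{block.n_atoms}", jpos)
    return block


# ---------------------------------------------------------------------------
# Geometry: locant path + closure search
# ---------------------------------------------------------------------------

@dataclass
class LocantPath:
    """The atom numbering of a solved ring system.

    ``n_atoms`` atoms are numbered 1..n along the path (bridge atoms last,
    off-path); ``edges`` is the full ring-bond set, ``rings`` one atom-index
    list per declared sub-ring (in declaration order).
    """

    n_atoms: int
    n_path: int                       # atoms actually on the path
    edges: list[tuple[int, int]]
    rings: list[list[int]]

    @property
    def share(self) -> dict[int, int]:
        counts = {a: 0 for a in range(1, self.n_atoms + 1)}
        for ring in self.rings:
            for a in ring:
                counts[a] += 1
        return counts


def _pair_locant_sum(rings: list[list[int]]) -> int:
    total = 0
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            total += sum(set(rings[i]) & set(rings[j]))
    return total


class _Solver:
    """Backtracking assembly of a ring system from its declared sub-rings.

    State: ``m`` atoms placed (path bonds i..i+1 implicit between on-path
    atoms), a set of extra (closure / bridge) bonds, and the rings fixed so
    far.  For each declared sub-ring a cycle of the declared size with the
    declared lowest locant is searched; it may walk existing bonds, append
    new path atoms at the path end, introduce exactly one new closure bond,
    and (within the declared bridge budget) route through new off-path
    bridge atoms.  Solutions must hit the declared system size and the
    declared multicyclic points exactly; the locant-sum-minimal solution
    wins.
    """

    def __init__(self, entries: list[RingEntry], n_target: int,
                 multi: list[int], bridges: list[int] | None = None):
        self.entries = entries
        self.n_target = n_target
        self.multi = sorted(multi)
        self.bridges = list(bridges or [])
        self.n_bridges = len(self.bridges)
        self.best: tuple | None = None

    def solve(self) -> LocantPath:
        self._recurse(0, max(1, self.entries[0].locant), frozenset(), [], 0)
        if self.best is None:
            raise NoLocantPath(
                "no locant path satisfies the declared ring system")
        _, m, extra, rings, nb = self.best
        n_path = m - nb
        # bridge atoms carry negative placeholder ids during the search and
        # take the highest locants in the final numbering
        remap = lambda a: a if a > 0 else n_path - a  # noqa: E731
        edges = [(i, i + 1) for i in range(1, n_path)]
        edges += sorted(tuple(sorted((remap(x), remap(y)))) for x, y in extra)
        rings = [[remap(a) for a in ring] for ring in rings]
        return LocantPath(m, n_path, edges, rings)

    # -- helpers -----------------------------------------------------------
    def _neighbours(self, a: int, n_path: int, extra: frozenset) -> list[int]:
        out = []
        if 1 <= a <= n_path:
            if a > 1:
                out.append(a - 1)
            if a + 1 <= n_path:
                out.append(a + 1)
        for (x, y) in extra:
            if x == a:
                out.append(y)
            elif y == a:
                out.append(x)
        return out

    def _recurse(self, idx: int, m: int, extra: frozenset,
                 rings: list, nb: int) -> None:
        if m > self.n_target:
            return
        if idx == len(self.entries):
            self._finish(m, extra, rings, nb)
            return
        entry = self.entries[idx]
        if entry.locant > m:
            return
        seen: set = set()
        for cycle, m2, extra2, nb2 in self._cycles(entry, m, extra, nb):
            key = (frozenset(cycle), extra2, m2)
            if key in seen:
                continue
            seen.add(key)
            self._recurse(idx + 1, m2, extra2, rings + [cycle], nb2)

    def _cycles(self, entry: RingEntry, m: int, extra: frozenset, nb: int):
        """Candidate cycles for one declared sub-ring (see class docstring)."""
        s, lo = entry.size, entry.locant
        results: list[tuple] = []

        def path_adjacent(a: int, b: int, n_path: int) -> bool:
            return 1 <= a <= n_path and 1 <= b <= n_path and abs(a - b) == 1

        def dfs(path: list[int], cur_m: int, cur_extra: frozenset,
                cur_nb: int, closures: int, bridge_edges: int) -> None:
            cur = path[-1]
            n_path = cur_m - cur_nb
            if len(path) == s:
                start = path[0]
                if start in self._neighbours(cur, n_path, cur_extra):
                    if closures + bridge_edges >= 1:
                        results.append((list(path), cur_m, cur_extra, cur_nb))
                elif closures == 0 and not path_adjacent(cur, start, n_path):
                    e = (min(cur, start), max(cur, start))
                    if e not in cur_extra:
                        results.append((list(path), cur_m,
                                        cur_extra | frozenset({e}), cur_nb))
                return
            for nxt in self._neighbours(cur, n_path, cur_extra):
                if (nxt > lo or nxt < 0) and nxt not in path:
                    dfs(path + [nxt], cur_m, cur_extra, cur_nb,
                        closures, bridge_edges)
            if cur == n_path and cur_m < self.n_target:
                # append a new path atom at the path end
                dfs(path + [n_path + 1], cur_m + 1, cur_extra, cur_nb,
                    closures, bridge_edges)
            if closures == 0:
                for nxt in range(lo + 1, n_path + 1):
                    if nxt in path or path_adjacent(cur, nxt, n_path):
                        continue
                    if nxt in self._neighbours(cur, n_path, cur_extra):
                        continue
                    e = (min(cur, nxt), max(cur, nxt))
                    dfs(path + [nxt], cur_m, cur_extra | frozenset({e}),
                        cur_nb, 1, bridge_edges)
            if cur_nb < self.n_bridges and cur_m < self.n_target:
                z = -(cur_nb + 1)      # placeholder id; renumbered at the end
                if z not in path:
                    e = (min(cur, z), max(cur, z))
                    dfs(path + [z], cur_m + 1, cur_extra | frozenset({e}),
                        cur_nb + 1, closures, bridge_edges + 1)

        dfs([lo], max(m, lo), extra, nb, 0, 0)
        return results

    def _finish(self, m: int, extra: frozenset, rings: list, nb: int) -> None:
        if m != self.n_target or nb != self.n_bridges:
            return
        counts: dict[int, int] = {}
        for ring in rings:
            for a in ring:
                counts[a] = counts.get(a, 0) + 1
        if len(counts) != m:
            return                      # every atom must sit in a sub-ring
        n_path = m - nb
        # every bridge atom must be bonded to its declared bridge locant
        if self.bridges:
            neigh = {z: set() for z in range(-1, -nb - 1, -1)}
            for (x, y) in extra:
                if x in neigh:
                    neigh[x].add(y)
                if y in neigh:
                    neigh[y].add(x)
            remaining = list(self.bridges)
            for z in sorted(neigh, reverse=True):
                hit = next((b for b in remaining if b in neigh[z]), None)
                if hit is None:
                    return
                remaining.remove(hit)
        remap = lambda a: a if a > 0 else n_path - a  # noqa: E731
        multi_found = sorted(remap(a) for a, k in counts.items() if k >= 3)
        if multi_found != self.multi:
            return
        mapped = [[remap(a) for a in ring] for ring in rings]
        score = (_pair_locant_sum(mapped),
                 tuple(tuple(r) for r in mapped), tuple(sorted(extra)))
        if self.best is None or score < self.best[0]:
            self.best = (score, m, extra, rings, nb)


@lru_cache(maxsize=512)
def _solve_cached(entries_key: tuple, n_target: int, multi: tuple,
                  bridges: tuple) -> LocantPath:
    entries = [RingEntry(lo, s) for (lo, s) in entries_key]
    return _Solver(entries, n_target, list(multi), list(bridges)).solve()


def build_locant_path(block: RingBlock) -> LocantPath:
    """Solve the declared ring system into a locant path plus ring bonds."""
    try:
        return _solve_cached(
            tuple((e.locant, e.size) for e in block.entries),
            block.n_atoms, tuple(block.multicyclic_points),
            tuple(block.bridges))
    except NoLocantPath:
        raise NoLocantPath(
            "no locant path satisfies the declared ring system",
            block.j_position) from None


# ---------------------------------------------------------------------------
# Ring system construction (graph side)
# ---------------------------------------------------------------------------

@dataclass
class RingSystem:
    """A built ring system: nodes in locant order plus ring metadata."""

    nodes: list            # WLNNode, list index i -> locant index i+1
    path: LocantPath
    aromatic: list[bool]   # per declared sub-ring
    rings: list[list[int]]
    block: RingBlock | None = None

    def node_at(self, locant_index: int, position: int | None = None):
        if not 1 <= locant_index <= len(self.nodes):
            raise BadLocant(
                f"locant index {locant_index} is off the ring system "
                f"(size {len(self.nodes)})", position)
        return self.nodes[locant_index - 1]


def build_ring_system(graph, block: RingBlock) -> RingSystem:
    """Materialise a parsed ring block as atoms and bonds in ``graph``."""
    path = build_locant_path(block)
    aromatic = block.ring_aromatic()
    nodes = []
    for _ in range(path.n_atoms):
        node = graph.new_node("C", source_char=block.opener,
                              source_position=block.j_position, max_conn=4)
        node.is_ring_member = True
        nodes.append(node)
    for (a, b) in path.edges:
        graph.add_edge(nodes[a - 1].id, nodes[b - 1].id, 1)
    for (a, b) in block.crossed:
        if a > path.n_atoms or b > path.n_atoms:
            raise BadLocant("crossed-bond locant off the ring system",
                            block.j_position)
        graph.add_edge(nodes[a - 1].id, nodes[b - 1].id, 1)
    for loc, char in block.hetero:
        elem, charge, min_h = _RING_ELEMENT[char]
        node = nodes[loc - 1]
        node.element = elem
        node.formal_charge = charge
        node.min_hydrogens = min_h
        node.source_char = char
        if char == "V":
            node.ring_carbonyl = True
        if char == "X":
            node.never_aromatic = True
    for loc, partner in block.unsats:
        if partner is None:
            partner = loc + 1 if loc + 1 <= path.n_path else 1
        if loc > path.n_atoms or partner > path.n_atoms:
            raise BadLocant("unsaturation locant off the ring system",
                            block.j_position)
        graph.set_order(nodes[loc - 1].id, nodes[partner - 1].id, 2)
    for flag, ring in zip(aromatic, path.rings):
        if flag:
            for a in ring:
                if not nodes[a - 1].never_aromatic:
                    nodes[a - 1].aromatic = True
    return RingSystem(nodes, path, aromatic, path.rings, block)


def build_benzene(graph, position: int) -> RingSystem:
    """The inline benzene shorthand ``R``: a six-membered aromatic ring."""
    block = RingBlock(opener="L", text="L6J", j_position=position)
    block.entries.append(RingEntry(1, 6))
    return build_ring_system(graph, block)
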