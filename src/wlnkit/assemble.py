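"""From WLN graph to chemistry: expansion, unsaturation, kekulization, output.

The pipeline mirrors how the notation is defined:

1. *shorthand expansion* -- ``W`` adds two double-bonded oxygens to its
   neighbour, ``V`` its carbonyl oxygen, and the methyl-filling symbols
   ``X``/``Y``/``K`` top up unused branch slots with methyl groups;
2. *implied unsaturation* (on by default, switchable off) -- two adjacent
   ``O`` symbols with free valence imply a double bond (so ``OO`` is O=O and
   the peroxide dianion has no plain WLN spelling), and the full-valence
   carbon ``C`` receives the double/triple bonds needed to reach valence 4;
3. *kekulization* -- WLN's relaxed aromaticity: a flagged ring is aromatic if
   it carries the maximum number of double bonds placeable after heteroatom
   assignment, i.e. a maximum matching over ring atoms with a free valence
   slot (augmenting-path matching on bipartite ring graphs, blossom matching
   otherwise); unmatched eligible atoms keep an implicit hydrogen instead.
   Hueckel's rule is deliberately not enforced;
4. *connection table* -- atoms, bonds, charges and implicit hydrogen counts
   in source order, handed to RDKit for canonical SMILES or InChI output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ParseError, ValenceError
from .parser import WLNGraph, WLNNode, parse

_VALENCE_ADJUST = {("N", 1): 4, ("N", -1): 2, ("O", 1): 3, ("O", -1): 1,
                   ("S", 1): 3, ("S", -1): 1, ("B", -1): 4, ("P", 1): 4}


def _periodic():
    from rdkit import Chem

    return Chem.GetPeriodicTable()


def _valence_options(element: str, charge: int) -> list[int]:
    if (element, charge) in _VALENCE_ADJUST:
        return [_VALENCE_ADJUST[(element, charge)]]
    pt = _periodic()
    opts = [v for v in pt.GetValenceList(element) if v >= 0]
    if not opts or opts == [-1]:
        opts = [pt.GetDefaultValence(element)]
    return sorted(opts)


def _capacity(g: WLNGraph, node: WLNNode) -> int:
    """Free valence slots beyond current bonds and guaranteed hydrogens."""
    opts = _valence_options(node.element, node.formal_charge)
    return max(opts) - g.bond_order_sum(node.id) - node.min_hydrogens


# ---------------------------------------------------------------------------
# 1. shorthand expansion
# ---------------------------------------------------------------------------

def expand_shorthand(g: WLNGraph) -> WLNGraph:
    """Expand condensed symbols into explicit atoms and bonds (in place)."""
    for node in list(g.nodes):
        if node.source_char == "W" and node.element is None:
            neigh = g.neighbours(node.id)
            if len(neigh) != 1:
                raise ValenceError("'W' needs exactly one neighbouring atom",
                                   node.source_position)
            target = g.nodes[neigh[0][0]]
            g.edges = [e for e in g.edges if node.id not in (e[0], e[1])]
            for _ in range(2):
                o = g.new_node("O", "W", node.source_position, max_conn=2)
                g.add_edge(target.id, o.id, 2)
            if _capacity(g, target) < 0 and target.element not in ("N", "S", "P"):
                raise ValenceError(
                    f"'W' overloads the valence of {target.element}",
                    node.source_position)
        elif node.source_char == "V" or node.ring_carbonyl:
            o = g.new_node("O", "V", node.source_position, max_conn=2)
            g.add_edge(node.id, o.id, 2)
            node.ring_carbonyl = False
    for node in list(g.nodes):
        if node.fill_methyl:
            for _ in range(max(0, node.max_conn - g.degree(node.id))):
                c = g.new_node("C", node.source_char, node.source_position,
                               max_conn=4)
                g.add_edge(node.id, c.id, 1)
            node.fill_methyl = False
    return g


# ---------------------------------------------------------------------------
# 2. implied unsaturation
# ---------------------------------------------------------------------------

def apply_implied_unsaturation(g: WLNGraph, implied: bool = True) -> WLNGraph:
    """Resolve implied double/triple bonds (the ``OO`` and ``C`` rules)."""
    if not implied:
        return g
    for e in g.edges:
        a, b = g.nodes[e[0]], g.nodes[e[1]]
        if (a.source_char == "O" and b.source_char == "O" and e[2] == 1
                and not a.is_ring_member and not b.is_ring_member
                and _capacity(g, a) >= 1 and _capacity(g, b) >= 1):
            e[2] = 2
    for node in g.nodes:
        if not node.must_unsaturate:
            continue
        deficit = 4 - g.bond_order_sum(node.id)
        # raise bond orders, preferring the following (higher-id) neighbour
        for nb_id, _ in sorted(g.neighbours(node.id), reverse=True):
            if deficit <= 0:
                break
            partner = g.nodes[nb_id]
            for e in g.edges:
                if {e[0], e[1]} == {node.id, nb_id}:
                    room = min(deficit, 3 - e[2],
                               max(0, _capacity(g, partner)))
                    e[2] += room
                    deficit -= room
                    break
        if deficit > 0:
            raise ValenceError(
                "no legal bond-order assignment for full-valence 'C'",
                node.source_position)
    return g


# ---------------------------------------------------------------------------
# 3. kekulization by maximum matching
# ---------------------------------------------------------------------------

def kekulize(g: WLNGraph, order: list[int] | None = None) -> WLNGraph:
    """Place alternating double bonds on aromatic-flagged ring atoms.

    Eligible atoms are aromatic ring members with at least one free valence
    slot; the maximum matching over the eligible ring subgraph becomes the
    set of double bonds.  ``order`` optionally permutes node insertion (used
    to check that canonical output is invariant to matching tie-breaks).
    """
    eligible = {n.id for n in g.nodes
                if n.aromatic and not n.closed and _capacity(g, n) >= 1}
    if not eligible:
        return g
    sub = nx.Graph()
    ids = sorted(eligible) if order is None else [i for i in order
                                                 if i in eligible]
    sub.add_nodes_from(ids)
    for a, b, o in g.edges:
        if o == 1 and a in eligible and b in eligible \
                and g.nodes[a].is_ring_member and g.nodes[b].is_ring_member:
            sub.add_edge(a, b)
    matched: set[tuple[int, int]] = set()
    for comp in nx.connected_components(sub):
        csub = sub.subgraph(comp)
        if csub.number_of_edges() == 0:
            continue
        if nx.is_bipartite(csub):
            top, _ = nx.bipartite.sets(csub)
            pairing = nx.bipartite.hopcroft_karp_matching(csub, top)
            matched.update((a, b) for a, b in pairing.items() if a < b)
        else:
            matched.update((min(a, b), max(a, b))
                           for a, b in nx.max_weight_matching(
                               csub, maxcardinality=True))
    for e in g.edges:
        if (min(e[0], e[1]), max(e[0], e[1])) in matched:
            e[2] = 2
    return g


def matching_size(g: WLNGraph) -> int:
    """Number of double bonds the kekulization placed (for diagnostics)."""
    return sum(1 for a, b, o in g.edges
               if o == 2 and g.nodes[a].aromatic and g.nodes[b].aromatic
               and g.nodes[a].is_ring_member and g.nodes[b].is_ring_member)


# ---------------------------------------------------------------------------
# 4. connection table and toolkit output
# ---------------------------------------------------------------------------

@dataclass
class CTAtom:
    element: str
    formal_charge: int
    implicit_hydrogens: int
    aromatic_member: bool
    source_position: int


@dataclass
class ConnectionTable:
    """Final atom/bond adjacency (the historical SCT XI role)."""

    atoms: list[CTAtom] = field(default_factory=list)
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    components: list[list[int]] = field(default_factory=list)


def _charge_separate(g: WLNGraph) -> None:
    """Neutral hypervalent nitrogen (e.g. nitro) becomes N+ / O-."""
    for node in g.nodes:
        if node.element != "N":
            continue
        while g.bond_order_sum(node.id) > 3 + node.formal_charge:
            for e in g.edges:
                a, b = e[0], e[1]
                if node.id in (a, b) and e[2] == 2:
                    other = g.nodes[b if a == node.id else a]
                    if other.element == "O" and other.formal_charge == 0 \
                            and g.degree(other.id) == 1:
                        e[2] = 1
                        other.formal_charge = -1
                        node.formal_charge += 1
                        break
            else:
                break


def build_connection_table(g: WLNGraph) -> ConnectionTable:
    """Materialise atoms, bonds and implicit hydrogens in source order."""
    _charge_separate(g)
    ct = ConnectionTable()
    index: dict[int, int] = {}
    for node in g.nodes:
        if node.element is None:
            if g.degree(node.id):
                raise ParseError("unexpanded symbol in the WLN graph",
                                 node.source_position)
            continue
        bond_sum = g.bond_order_sum(node.id)
        opts = _valence_options(node.element, node.formal_charge)
        val = next((v for v in opts if v >= bond_sum + node.min_hydrogens),
                   None)
        if val is None:
            raise ValenceError(
                f"atom {node.element} (from {node.source_char!r}) exceeds "
                f"its allowed valence", node.source_position)
        ih = 0 if node.element == "H" else val - bond_sum
        index[node.id] = len(ct.atoms)
        ct.atoms.append(CTAtom(node.element, node.formal_charge, ih,
                               node.aromatic, node.source_position))
    for a, b, o in g.edges:
        if a in index and b in index:
            ct.bonds.append((index[a], index[b], o))
    seen: set[int] = set()
    adj: dict[int, list[int]] = {i: [] for i in range(len(ct.atoms))}
    for a, b, _ in ct.bonds:
        adj[a].append(b)
        adj[b].append(a)
    for i in range(len(ct.atoms)):
        if i in seen:
            continue
        comp, todo = [], [i]
        while todo:
            x = todo.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            todo.extend(adj[x])
        ct.components.append(sorted(comp))
    return ct


def to_rdkit(ct: ConnectionTable):
    """Build a sanitized RDKit molecule from a connection table."""
    from rdkit import Chem

    mol = Chem.RWMol()
    for atom in ct.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNumExplicitHs(atom.implicit_hydrogens)
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    orders = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE, 0: Chem.BondType.DATIVE}
    for a, b, o in ct.bonds:
        mol.AddBond(a, b, orders[o])
    m = mol.GetMol()
    try:
        Chem.SanitizeMol(m)
        m = Chem.RemoveHs(m)
    except Exception as exc:  # rdkit raises plain Exceptions
        raise ValenceError(f"residual valence violation: {exc}") from None
    return m


# ---------------------------------------------------------------------------
# end-to-end conversion
# ---------------------------------------------------------------------------

def graph_to_mol(g: WLNGraph, implied: bool = True,
                 matching_order: list[int] | None = None):
    expand_shorthand(g)
    apply_implied_unsaturation(g, implied=implied)
    kekulize(g, order=matching_order)
    return to_rdkit(build_connection_table(g))


def convert(wln: str, fmt: str = "smiles", implied: bool = True,
            strict: bool = False,
            matching_order: list[int] | None = None) -> str:
    """Convert a WLN string to canonical SMILES (default) or InChI."""
    from rdkit import Chem

    g = parse(wln, recover=not strict)
    mol = graph_to_mol(g, implied=implied, matching_order=matching_order)
    if fmt == "smiles":
        return Chem.MolToSmiles(mol)
    if fmt == "inchi":
        from rdkit.Chem import inchi

        return inchi.MolToInchi(mol)
    raise ValueError(f"unknown output format {fmt!r}")
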