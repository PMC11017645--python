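"""Shorthand expansion, implied unsaturation, kekulization, conversion."""

import random
from itertools import combinations

import pytest

from wlnkit.assemble import (apply_implied_unsaturation, convert,
                             expand_shorthand, graph_to_mol, kekulize,
                             matching_size)
from wlnkit.errors import ValenceError
from wlnkit.parser import parse


@pytest.mark.parametrize("wln,smiles", [
    ("QQ", "OO"),                    # hydrogen peroxide
    ("1NW", "C[N+](=O)[O-]"),        # nitromethane (charge-separated)
    ("1V1", "CC(C)=O"),              # acetone
    ("X", "CC(C)(C)C"),              # methyl fill on X
    ("K", "C[N+](C)(C)C"),           # K: charged N with methyl fill
])
def test_expand_shorthand_examples(wln, smiles, can):
    assert convert(wln) == can(smiles)


@pytest.mark.parametrize("wln,smiles", [
    ("OO", "O=O"),                   # adjacent O symbols imply a double bond
    ("SCN", "SC#N"),                 # implied triple bond at 'C'
    ("1UU1", "C#C"),
])
def test_implied_unsaturation_default(wln, smiles, can):
    assert convert(wln) == can(smiles)


def test_implied_unsaturation_flag_off(can):
    assert convert("OO", implied=False) == can("[OH][OH]")
    assert convert("OO") == can("O=O")


def test_flag_monotonicity(smith_pairs):
    """Disabling implied double bonds never increases any bond order."""
    for wln in ("OO", "SCN", "Q1XGG2Y1Q1Z", "1V1"):
        g_on = parse(wln)
        expand_shorthand(g_on)
        apply_implied_unsaturation(g_on, implied=True)
        g_off = parse(wln)
        expand_shorthand(g_off)
        apply_implied_unsaturation(g_off, implied=False)
        for e_on, e_off in zip(g_on.edges, g_off.edges):
            assert e_off[2] <= e_on[2]


# ---------------------------------------------------------------------------
# kekulization
# ---------------------------------------------------------------------------

def brute_force_max_matching(nodes, edges):
    """Largest set of vertex-disjoint edges, by exhaustive enumeration."""
    best = 0
    for k in range(len(edges), 0, -1):
        if k <= best:
            break
        for combo in combinations(edges, k):
            used = [v for e in combo for v in e]
            if len(used) == len(set(used)):
                best = max(best, k)
                break
    return best


def _ring_subgraph(wln):
    g = parse(wln)
    expand_shorthand(g)
    apply_implied_unsaturation(g)
    from wlnkit.assemble import _capacity

    eligible = {n.id for n in g.nodes if n.aromatic and _capacity(g, n) >= 1}
    edges = [(a, b) for a, b, o in g.edges
             if o == 1 and a in eligible and b in eligible]
    kekulize(g)
    return g, eligible, edges


@pytest.mark.parametrize("wln,expected", [
    ("L6J", 3),          # benzene: perfect matching on an even cycle
    ("T5MJ", 2),         # pyrrole-type ring: N-H is ineligible
    ("T5NJ", 2),         # all-eligible odd ring still matches 2
    ("L57J", 5),         # azulene-type fused 5-7 system
    ("L66J", 5),
    ("L C666J", 7),
])
def test_matching_size_equals_brute_force(wln, expected):
    g, eligible, edges = _ring_subgraph(wln)
    assert matching_size(g) == expected
    assert matching_size(g) == brute_force_max_matching(eligible, edges)


def test_matching_size_brute_force_all_small_fixtures():
    for wln in ("L6J", "L66J", "T5OJ", "T5SJ", "T6NJ", "T6NNJ", "T6N CNJ",
                "T5MNJ", "L57J", "T66 BNJ"):
        g, eligible, edges = _ring_subgraph(wln)
        assert matching_size(g) == brute_force_max_matching(eligible, edges), wln


def test_canonical_output_invariant_to_matching_tie_breaks(can):
    rng = random.Random(11)
    for wln in ("L6J", "L66J", "L C666J", "T6NJ", "L57J"):
        ref = convert(wln)
        for _ in range(5):
            g = parse(wln)
            order = [n.id for n in g.nodes]
            rng.shuffle(order)
            assert convert(wln, matching_order=order) == ref


def test_unmatched_eligible_atom_gains_hydrogen():
    # 13-atom perifused system (phenalene): 13 eligible atoms, matching 6,
    # so exactly one ring atom stays CH2
    from rdkit import Chem

    out = convert("L666 1A MJ")
    mol = Chem.MolFromSmiles(out)
    assert mol.GetNumAtoms() == 13
    assert sum(1 for a in mol.GetAtoms() if a.GetTotalNumHs() == 2) == 1


# ---------------------------------------------------------------------------
# connection table and end-to-end conversion
# ---------------------------------------------------------------------------

def test_connection_table_fig17():
    from wlnkit.assemble import build_connection_table

    g = parse("Q1XGG2Y1Q1Z")
    expand_shorthand(g)
    apply_implied_unsaturation(g)
    ct = build_connection_table(g)
    assert len(ct.atoms) == 12
    assert len(ct.bonds) == 11
    assert all(o == 1 for _, _, o in ct.bonds)
    assert len(ct.components) == 1


def test_connection_table_ions():
    from wlnkit.assemble import build_connection_table

    g = parse("Z2Z &GH")
    expand_shorthand(g)
    apply_implied_unsaturation(g)
    ct = build_connection_table(g)
    assert len(ct.components) == 2


def test_valence_error_names_position():
    with pytest.raises(ValenceError):
        convert("QW")        # W cannot put two =O on a hydroxyl oxygen


def test_convert_is_deterministic():
    wln = "T-T665 B6 2AB O KO NUT &TTJ IQ MQ B2N1 &- D6J"
    assert convert(wln) == convert(wln)


def test_inchi_output():
    inchi = convert("SCN", fmt="inchi")
    assert inchi.startswith("InChI=1S/CHNS/")


def test_valence_conservation_on_dataset(smith_pairs):
    """Every successfully converted string yields a sanitizable molecule
    whose atoms satisfy their standard valences."""
    from rdkit import Chem

    for wln, _ in smith_pairs:
        g = parse(wln)
        mol = graph_to_mol(g)
        problems = Chem.DetectChemistryProblems(mol)
        assert not problems, wln
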