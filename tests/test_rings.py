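"""Ring blocks: clause parsing, locant paths, assembly properties."""

from itertools import permutations

import pytest

from wlnkit.errors import BadLocant, RingParseError
from wlnkit.rings import (LocantPath, RingBlock, build_locant_path,
                          parse_ring_block)


def test_anthracene_block_fields():
    block = parse_ring_block("L C666J")
    assert block.opener == "L"
    assert [(e.locant, e.size) for e in block.entries] == [(3, 6), (1, 6), (1, 6)]
    assert block.entries[0].explicit_locant
    assert block.ring_aromatic() == [True, True, True]


def test_single_ring_and_aliphatic_flag():
    assert [(e.locant, e.size) for e in parse_ring_block("L6J").entries] == [(1, 6)]
    block = parse_ring_block("L6TJ")
    assert block.ring_aromatic() == [False]


def test_pyridine_implied_heteroatom_position():
    block = parse_ring_block("T6NJ")
    assert block.hetero == [(1, "N")]
    # consecutive bare heteroatoms advance the implied position
    assert parse_ring_block("T6NNJ").hetero == [(1, "N"), (2, "N")]
    # an explicit locant resets it
    assert parse_ring_block("T6N CNJ").hetero == [(1, "N"), (3, "N")]


def test_multicyclic_clause():
    block = parse_ring_block("T665 B6 2AB O KO NUT &TTJ")
    assert [(e.locant, e.size) for e in block.entries] == \
        [(1, 6), (1, 6), (1, 5), (2, 6)]
    assert block.multicyclic_points == [1, 2]
    assert block.system_size == 15
    assert (11, "O") in block.hetero
    assert (14, None) in block.unsats
    assert block.ring_aromatic() == [False, True, False, False]


def test_crossed_bond_clause():
    block = parse_ring_block("L6 6/BEJ")
    assert block.crossed == [(2, 5)]


def test_substituent_locant_off_path_rejected():
    from wlnkit.parser import parse

    with pytest.raises(BadLocant):
        parse("L6J I1")                 # locant I=9 on a 6-ring


def test_ambiguous_small_locant_falls_back_to_elements():
    # 'P' cannot index a 6-ring, so "PN" reads as two heteroatoms
    assert parse_ring_block("T6 PNJ").hetero == [(1, "P"), (2, "N")]


def test_flag_count_mismatch_rejected():
    block = parse_ring_block("L66 &&&J")
    with pytest.raises(RingParseError):
        block.ring_aromatic()


def test_error_points_at_closing_j():
    text = "L66 &&&J"
    with pytest.raises(RingParseError) as exc:
        parse_ring_block(text, offset=10).ring_aromatic()
    assert exc.value.position == 10 + len(text) - 1


# ---------------------------------------------------------------------------
# locant path properties
# ---------------------------------------------------------------------------

def _path_graph(path: LocantPath):
    adj = {a: set() for a in range(1, path.n_atoms + 1)}
    for a, b in path.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _hamiltonian_paths(adj, nodes):
    """All Hamiltonian paths over ``nodes`` (exhaustive, small systems)."""
    found = []

    def extend(seq, remaining):
        if not remaining:
            found.append(list(seq))
            return
        for nxt in sorted(adj[seq[-1]] & remaining):
            extend(seq + [nxt], remaining - {nxt})

    for start in nodes:
        extend([start], set(nodes) - {start})
    return found


@pytest.mark.parametrize("block_text", [
    "L6J", "L66J", "L C666J", "L B666J", "T665 B6 2AB O KO NUT &TTJ",
])
def test_locant_path_is_hamiltonian_with_max_share_start(block_text):
    path = build_locant_path(parse_ring_block(block_text))
    adj = _path_graph(path)
    on_path = list(range(1, path.n_path + 1))
    # the numbering 1..n_path is itself a Hamiltonian path over ring bonds
    for a, b in zip(on_path, on_path[1:]):
        assert b in adj[a]
    # the start atom carries the maximal ring-share count
    share = path.share
    assert share[1] == max(share[a] for a in on_path)
    # and an exhaustive search confirms a Hamiltonian path exists that the
    # numbering realises (systems here are <= 16 atoms)
    if path.n_atoms <= 14 and path.n_path == path.n_atoms:
        assert on_path in _hamiltonian_paths(adj, on_path)


@pytest.mark.parametrize("block_text,n_atoms", [
    ("L6J", 6), ("L66J", 10), ("L C666J", 14),
    ("T665 B6 2AB O KO NUT &TTJ", 15), ("L55 ATJ", 7),
])
def test_atom_conservation(block_text, n_atoms):
    block = parse_ring_block(block_text)
    path = build_locant_path(block)
    assert path.n_atoms == n_atoms == block.n_atoms


@pytest.mark.parametrize("block_text", ["L66J", "L C666J", "L55 ATJ",
                                        "T665 B6 2AB O KO NUT &TTJ"])
def test_subring_size_conservation(block_text):
    block = parse_ring_block(block_text)
    path = build_locant_path(block)
    adj = _path_graph(path)
    for entry, ring in zip(block.entries, path.rings):
        assert len(ring) == entry.size
        assert min(ring) == entry.locant
        cyc = ring + [ring[0]]
        for a, b in zip(cyc, cyc[1:]):   # the ring is an actual cycle
            assert b in adj[a]


def test_naphthalene_fusion_atoms_are_a_and_f():
    path = build_locant_path(parse_ring_block("L66J"))
    share = path.share
    assert sorted(a for a, k in share.items() if k == 2) == [1, 6]


def test_multicyclic_points_validated():
    path = build_locant_path(parse_ring_block("T665 B6 2AB O KO NUT &TTJ"))
    share = path.share
    assert sorted(a for a, k in share.items() if k >= 3) == [1, 2]


def test_locant_sum_minimality_on_small_fused_systems():
    """Among all Hamiltonian numberings consistent with the declaration,
    the chosen one minimises the pairwise shared-locant sum (naphthalene)."""
    path = build_locant_path(parse_ring_block("L66J"))
    chosen = sum(a for a, k in path.share.items() if k == 2)
    assert chosen == 7          # locants A (1) + F (6): the minimum


def test_no_locant_path_raises():
    from wlnkit.errors import NoLocantPath

    block = parse_ring_block("L6J")
    block.system_size = 9       # inconsistent declaration
    with pytest.raises(NoLocantPath):
        build_locant_path(block)
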