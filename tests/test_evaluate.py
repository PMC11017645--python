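"""Benchmark methodology: stereo stripping, comparison, triage, summaries."""

import random

import pytest

from wlnkit.errors import RecordError
from wlnkit.evaluate import (BenchmarkRecord, compare_canonical,
                             run_benchmark, similarity, strip_stereo,
                             summarize, triage)


@pytest.mark.parametrize("smiles,plain", [
    ("N[C@@H](C)C(=O)O", "NC(C)C(=O)O"),
    ("CCO", "CCO"),
    ("F/C=C/F", "FC=CF"),
])
def test_strip_stereo(smiles, plain, can):
    assert strip_stereo(smiles) == can(plain)


def test_strip_stereo_preserves_atom_and_bond_counts():
    from rdkit import Chem

    before = Chem.MolFromSmiles("N[C@@H](C)C(=O)O")
    after = Chem.MolFromSmiles(strip_stereo("N[C@@H](C)C(=O)O"))
    assert before.GetNumAtoms() == after.GetNumAtoms()
    assert before.GetNumBonds() == after.GetNumBonds()


def test_strip_stereo_rejects_garbage():
    with pytest.raises(RecordError):
        strip_stereo("not-a-smiles")


def test_compare_canonical():
    from wlnkit.assemble import convert

    assert compare_canonical(convert("SCN"), "SC#N")
    assert compare_canonical("OCC(Cl)(Cl)CCC(CO)CN", "OCC(Cl)(Cl)CCC(CO)CN")
    # OO denotes molecular oxygen, not the peroxide dianion
    assert not compare_canonical(convert("OO"), "[O-][O-]")
    # stereo on the reference side is ignored
    assert compare_canonical("NC(C)C(=O)O", "N[C@@H](C)C(=O)O")


def test_similarity_bounds_and_identity():
    assert similarity("CCO", "CCO") == pytest.approx(1.0)
    s = similarity("CCO", "CCCO")
    assert 0.0 < s < 1.0


def test_similarity_equals_explicit_bit_set_tanimoto():
    from rdkit import Chem

    a = Chem.MolFromSmiles("CCO")
    b = Chem.MolFromSmiles("CCCO")
    fa = set(Chem.RDKFingerprint(a).GetOnBits())
    fb = set(Chem.RDKFingerprint(b).GetOnBits())
    expected = len(fa & fb) / len(fa | fb)
    assert similarity("CCO", "CCCO") == pytest.approx(expected)


# ---------------------------------------------------------------------------
# triage pipeline
# ---------------------------------------------------------------------------

def test_triage_exact_pass():
    r = triage(BenchmarkRecord("SCN", "SC#N"))
    assert r.status == "exact_pass"


def test_triage_partial_with_recovery_suggestion():
    r = triage(BenchmarkRecord("Z2Z & GH", "NCCN.Cl"))
    assert r.status == "partial"
    assert "Z2Z" in r.substrings and "GH" in r.substrings
    assert r.note


def test_triage_rejected_lowercase_junk():
    r = triage(BenchmarkRecord("mantrap4junk", "CC"))
    assert r.status == "rejected"


def test_triage_suffix_stripping():
    r = triage(BenchmarkRecord("Q2 &&beta form", "CCO"))
    assert r.status == "exact_pass"
    assert "beta form" in r.note


def test_triage_exact_fail_scores_similarity():
    r = triage(BenchmarkRecord("Q2", "CCCO"))    # valid WLN, wrong reference
    assert r.status == "exact_fail"
    assert r.similarity is not None and 0.0 <= r.similarity <= 1.0


def test_triage_statuses_are_exhaustive_and_exclusive():
    records = [
        BenchmarkRecord("SCN", "SC#N"),
        BenchmarkRecord("SCUUN", "SC#N"),
        BenchmarkRecord("Z2Z & GH", "NCCN.Cl"),
        BenchmarkRecord("mantrap...", "CC"),
        BenchmarkRecord("Q2", "CCCO"),
    ]
    for r in records:
        result = triage(r)
        assert result.status in {"exact_pass", "exact_fail", "partial",
                                 "rejected"}


# ---------------------------------------------------------------------------
# benchmark summaries
# ---------------------------------------------------------------------------

def test_run_benchmark_reference_set(smith_tsv):
    s = run_benchmark(smith_tsv)
    assert s.set_size == 69
    assert s.exact_matches == 69
    assert s.conversions_correct == 69
    assert s.status_counts == {"exact_pass": 69}


def test_run_benchmark_curation_set(curation_tsv):
    s = run_benchmark(curation_tsv)
    assert s.set_size == 10
    assert s.exact_matches < s.set_size
    assert s.status_counts["rejected"] == 1
    assert s.status_counts["partial"] == 3
    assert s.conversions_correct >= 7


def test_greedy_matches_at_least_exact_matches(smith_tsv, curation_tsv):
    for path in (smith_tsv, curation_tsv):
        s = run_benchmark(path)
        assert s.greedy_matches >= s.exact_matches


def test_summary_invariant_under_row_permutation(smith_tsv):
    from wlnkit.evaluate import read_benchmark

    records = read_benchmark(smith_tsv)
    base = summarize(records)
    rng = random.Random(3)
    shuffled = records[:]
    rng.shuffle(shuffled)
    perm = summarize(shuffled)
    assert base.as_dict() == perm.as_dict()


def test_malformed_rows_counted_and_rejected(tmp_path):
    p = tmp_path / "rows.tsv"
    p.write_text("SCN\tSC#N\nBROKENROW\n", encoding="utf-8")
    s = run_benchmark(str(p))
    assert s.set_size == 2
    assert s.conversions_correct == 1
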