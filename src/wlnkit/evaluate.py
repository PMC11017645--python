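"""Conversion benchmarking: reference comparison, triage and summaries.

Benchmark tables are two-column TSVs (``WLN<TAB>SMILES``, no header, UTF-8;
extra columns are ignored).  Each record runs through a four-step triage:

1. match the WLN string with the relaxed-grammar matcher (after stripping a
   historical ``&&`` annotation suffix);
2. if the whole string matches exactly, convert it and compare canonical
   SMILES with the reference;
3. if only substrings match, convert the extracted candidates against the
   reference and record the string with a correction suggestion;
4. otherwise flag the record as an incorrect WLN entry.

Comparison is a plain string equality of canonical SMILES from a single
toolkit (which also checks every implicit/explicit hydrogen); references are
stripped of stereochemistry first, since WLN carries essentially none.
Failed conversions get a Tanimoto similarity over a path-based fingerprint
so near-misses can be ranked for curation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import RecordError, WLNError
from .fsm import MatcherConfig, build_matcher, strip_annotation_suffix


def _chem():
    from rdkit import Chem

    return Chem


@dataclass
class BenchmarkRecord:
    wln: str
    reference: str        # SMILES


@dataclass
class TriageResult:
    status: str           # exact_pass | exact_fail | partial | rejected
    substrings: list[str] = field(default_factory=list)
    similarity: float | None = None
    output: str | None = None
    note: str = ""


@dataclass
class BenchmarkSummary:
    set_size: int = 0
    exact_matches: int = 0
    greedy_matches: int = 0
    conversions_correct: int = 0
    mean_failure_similarity: float | None = None
    status_counts: dict = field(default_factory=dict)
    failures: list[TriageResult] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "set_size": self.set_size,
            "exact_matches": self.exact_matches,
            "greedy_matches": self.greedy_matches,
            "conversions_correct": self.conversions_correct,
            "mean_failure_similarity": self.mean_failure_similarity,
            "status_counts": self.status_counts,
        }


def strip_stereo(smiles: str) -> str:
    """Canonical SMILES with all stereochemistry descriptors removed."""
    Chem = _chem()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise RecordError(f"unparseable reference SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def compare_canonical(out_smiles: str, ref_smiles: str) -> bool:
    """True iff both canonical forms are string-identical (stereo stripped)."""
    Chem = _chem()
    out_mol = Chem.MolFromSmiles(out_smiles)
    if out_mol is None:
        raise RecordError(f"unparseable output SMILES: {out_smiles!r}")
    return Chem.MolToSmiles(out_mol) == strip_stereo(ref_smiles)


def similarity(out_smiles: str, ref_smiles: str) -> float:
    """Tanimoto coefficient over path-based fingerprints of the two SMILES."""
    Chem = _chem()
    from rdkit import DataStructs

    a = Chem.MolFromSmiles(out_smiles)
    b = Chem.MolFromSmiles(ref_smiles)
    if a is None or b is None:
        raise RecordError("unparseable SMILES for similarity scoring")
    Chem.RemoveStereochemistry(b)
    fa, fb = Chem.RDKFingerprint(a), Chem.RDKFingerprint(b)
    return DataStructs.TanimotoSimilarity(fa, fb)


def triage(record: BenchmarkRecord) -> TriageResult:
    """The four-step wlngrep pipeline for one benchmark record."""
    from .assemble import convert

    matcher = build_matcher()
    wln, suffix = strip_annotation_suffix(record.wln)
    note = f"stripped annotation suffix {suffix!r}" if suffix else ""
    if matcher.match_exact(wln):
        try:
            out = convert(wln)
            if compare_canonical(out, record.reference):
                return TriageResult("exact_pass", [wln], output=out, note=note)
            sim = similarity(out, record.reference)
            return TriageResult("exact_fail", [wln], similarity=sim,
                                output=out,
                                note=note or "conversion differs from "
                                "the reference")
        except (WLNError, RecordError) as exc:
            return TriageResult("exact_fail", [wln], output=None,
                                note=f"{note + '; ' if note else ''}{exc}")
    spans = matcher.match_greedy(wln, MatcherConfig())
    subs = [s.text for s in spans]
    if subs:
        try:
            # run-time error recovery (symbol raising, OCR-space skipping)
            # may repair the full string even when exact matching fails
            out = convert(wln)
            if compare_canonical(out, record.reference):
                return TriageResult(
                    "partial", subs, output=out,
                    note="recovered by run-time error handling; suggest "
                    "correcting the source string")
        except (WLNError, RecordError):
            pass
        best_sim, out_all = None, None
        for sub in subs:
            try:
                out = convert(sub)
                if compare_canonical(out, record.reference):
                    return TriageResult(
                        "partial", subs, output=out,
                        note=f"valid substring {sub!r} matches the "
                        "reference; suggest correcting the full string")
                sim = similarity(out, record.reference)
                if best_sim is None or sim > best_sim:
                    best_sim, out_all = sim, out
            except (WLNError, RecordError):
                continue
        return TriageResult("partial", subs, similarity=best_sim,
                            output=out_all,
                            note=note or "only substrings are valid WLN")
    return TriageResult("rejected", [], note=note or
                        "not valid WLN notation; flagged as incorrect")


def read_benchmark(path: str) -> list[BenchmarkRecord]:
    """Read a WLN<TAB>SMILES table; malformed rows become empty references."""
    records: list[BenchmarkRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            records.append(BenchmarkRecord(parts[0],
                                           parts[1] if len(parts) > 1 else ""))
    return records


def run_benchmark(path: str) -> BenchmarkSummary:
    """Score a benchmark TSV with the full triage pipeline."""
    records = read_benchmark(path)
    return summarize(records)


def summarize(records: list[BenchmarkRecord]) -> BenchmarkSummary:
    matcher = build_matcher()
    summary = BenchmarkSummary(set_size=len(records))
    failure_sims: list[float] = []
    for record in records:
        wln, _ = strip_annotation_suffix(record.wln)
        if matcher.match_exact(wln):
            summary.exact_matches += 1
        # benchmark rows are known candidates, so lone-letter WLN strings
        # (e.g. "Q") count as greedy matches too
        spans = matcher.match_greedy(wln, MatcherConfig(allow_single_letter=True))
        summary.greedy_matches += len(spans)
        try:
            result = triage(record)
        except RecordError as exc:
            result = TriageResult("rejected", note=str(exc))
        summary.status_counts[result.status] = \
            summary.status_counts.get(result.status, 0) + 1
        correct = result.status == "exact_pass" or (
            result.status == "partial" and result.output is not None
            and result.similarity is None)
        if correct:
            summary.conversions_correct += 1
        else:
            if result.similarity is not None:
                failure_sims.append(result.similarity)
            summary.failures.append(
                TriageResult(result.status, [record.wln],
                             result.similarity, result.output, result.note))
    if failure_sims:
        summary.mean_failure_similarity = sum(failure_sims) / len(failure_sims)
    return summary


def write_report(summary: BenchmarkSummary, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary.as_dict(), fh, indent=2)
        fh.write("\n")


def write_failures(summary: BenchmarkSummary, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in summary.failures:
            sim = "" if f.similarity is None else f"{f.similarity:.3f}"
            out = f.output or ""
            fh.write(f"{f.substrings[0]}\t{f.status}\t{out}\t{sim}\t"
                     f"{f.note}\n")
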