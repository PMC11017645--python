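# wlnkit

Wiswesser Line Notation (WLN) was the dominant chemical line notation before
SMILES and InChI: molecules encoded as strings over `A–Z`, `0–9` and four
punctuation marks, typed on punch cards and distributed through decades of
indexes, catalogues and patents.  That data is still out there — in ChEMBL,
PubChem and ChemSpider records, and in scanned documents — but unreadable to
modern toolkits.

`wlnkit` is a toolkit for modernising it:

* **`wlngrep`** — a grammar-derived finite-state matcher that recognises and
  extracts candidate WLN strings from free text.  The WLN grammar is
  context-free (branches and ring closures must balance), so the matcher
  recognises a *relaxed* regular superset — any number of branches, any
  number of closures — compiled NFA → DFA (subset construction) → minimal
  DFA, and re-imposes the balancing rules with a pushdown stack at match
  time.  Exact mode validates whole lines; greedy mode extracts
  leftmost-longest valid substrings (single letters suppressed by default).
* **`readwln`** — a full parser that reads WLN character by character into a
  symbol graph, assembles ring systems from their locant paths, expands the
  condensed-group shorthands, resolves WLN's implied-double-bond
  conventions, kekulizes aromatic rings by maximum matching, and emits
  canonical SMILES or InChI (via RDKit).
* **`wlnbench`** — a benchmark harness that scores `WLN<TAB>SMILES` tables
  with a four-step triage (exact match → convert → extract substrings →
  flag as incorrect), canonical-SMILES string comparison, and Tanimoto
  similarity on failures for curation ranking.

The parser covers acyclic notation, benzene shorthand, monocyclic through
perifused and multicyclic ring systems, bridges, spiro fusions, chained
rings, macrocyclic return notation, element codes, ions, and the run-time
error recovery (symbol raising, OCR-space skipping) that legacy data needs.

## Worked example

Extract WLN from prose, then convert it:

```text
$ printf 'prepared Q1XGG2Y1Q1Z in two steps\n' | wlngrep -
Q1XGG2Y1Q1Z

$ printf 'SCN\nQ1XGG2Y1Q1Z\nL C666J\n' | readwln -
N#CS
NCC(CO)CCC(Cl)(Cl)CO
c1ccc2cc3ccccc3cc2c1
```

`SCN` is thiocyanic acid — the triple bond is *implied* by the full-valence
carbon symbol `C`; `Q1XGG2Y1Q1Z` is the branched chloro-amino-diol whose `X`
and `Y` symbols are branch points; `L C666J` is anthracene, built from a
14-atom locant path with three fused six-rings.  The same machinery handles
morphine in both of its published spellings (macrocyclic and multicyclic),
which convert to the same canonical SMILES:

```text
$ printf 'T-T665 B6 2AB O KO NUT &TTJ IQ MQ B2N1 &- D6J\n' | readwln -
CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5
```

Scoring a curation table (valid records, OCR faults, `&&` annotation
suffixes, lower-case junk):

```text
$ wlnbench src/wlnkit/data/synthetic_curation.tsv
records:             10
exact matches:       6
greedy matches:      12
conversions correct: 8 (80.0%)
```

As a library:

```python
>>> from wlnkit import convert, match_greedy
>>> convert("QQ"), convert("OO")      # hydroxyls vs implied double bond
('OO', 'O=O')
>>> [s.text for s in match_greedy("dissolved Z2Z &GH in water")]
['Z2Z &GH']
```

## Layout

| module | role |
|---|---|
| `wlnkit.symbols` | WLN character set, per-symbol semantics, locant arithmetic |
| `wlnkit.fsm` | NFA/DFA construction, minimization, stack-augmented matching |
| `wlnkit.parser` | character-by-character WLN graph construction, error recovery |
| `wlnkit.rings` | ring-block parsing, locant paths, ring-system assembly |
| `wlnkit.assemble` | shorthand expansion, implied unsaturation, kekulization, SMILES/InChI |
| `wlnkit.evaluate` | triage pipeline, canonical comparison, benchmark summaries |

See `docs/methods.md` for the underlying model, the reconstruction decisions
and known limitations.
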