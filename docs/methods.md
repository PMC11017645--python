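# Methods

## The notation and its formalisation

WLN encodes a molecular graph as a string over the upper-case letters,
digits, and the punctuation marks `&`, `-`, `/` and space.  Each letter
carries an acyclic meaning (element, condensed functional group, or ring
punctuation) plus a *WLN degree*: the number of branches the symbol may
take, counted as children in the parse tree rather than as a bond-order sum.
`wlnkit.symbols` is the single authority for these semantics; the table is
exported as a machine-readable fixture and diffed against an independent
transcription in the test suite.

Acyclic strings form trees: digits append alkyl chains (consecutive digits
are one number), terminator symbols close the current branch and return to
the last open branching symbol, `&` pops a branching level explicitly, `U`
(at most two in a row) raises the next bond's order, a space-ampersand
starts a new ion component, and `-XX-` embeds a two-letter periodic code.
The full-valence carbon `C` carries an *implied* unsaturation; an explicit
`U` next to it is redundant and treated as invalid (this is what makes
`SCUUN` a broken spelling of `SCN`).

## Matching: a relaxed regular language plus a stack

Balanced branches and ring closures make WLN context-free, so no DFA accepts
exactly the language.  The matcher therefore accepts a relaxed superset —
any number of branches after a symbol, any number of closures — as a
hand-built NFA over ~26 grammar states (chain, ring-block, post-ring-clause
and dash-clause contexts), determinized by subset construction and minimized
by partition refinement.  At match time a pushdown stack tracks open ring
blocks, a branch counter and a chain-termination latch, so that ring
closures never exceed opens, terminators end unbranched chains, and locant
clauses require a ring in the current component.  Semantic correctness
(valence, locant existence) is deliberately *not* the matcher's job; the
parser validates candidates afterwards, and every parser-accepted string is
matcher-accepted by construction (tested as the superset property).

The minimized machine here has 34 states and 972 edges.  The reference
machine built from the same idea is reported at 59 states and 1028 edges;
since the exact set of relaxations is a free design choice, only the order
of magnitude is comparable, and the sizes are recorded informationally
rather than asserted.

Greedy extraction returns leftmost-longest accepted substrings and then
continues scanning after each match; spans are 0-based half-open.  Matches
of length one are suppressed by default because most lone capitals are
themselves valid WLN strings ("water" is `Q`); a flag re-enables them.  The
letter `A` is locant-only and is not accepted as a compound even with the
flag.  In benchmark scoring (where every row is a known candidate, not free
text) greedy counting re-enables single-letter matches so that greedy
matches are never fewer than exact matches.

A historical annotation convention appends free text after a double
ampersand (`... TQ &&Alpha`); `strip_annotation_suffix` splits at the first
`" &&"` outside ring blocks before matching or conversion.

## Ring systems and the locant path

A ring block (`L`/`T`/`D` … `J`) declares, in order: sub-ring sizes, each
with an optional lowest locant (default `A`; sizes over 9 wrapped in
dashes); an optional multicyclic clause — the count and locants of atoms
shared by more than two sub-rings, then the system size as a locant;
heteroatom placements (explicit locant, or the position after the last
locant seen, starting at `A`); explicit ring unsaturations (`<locant>U`,
with `<locant>U- <locant>` naming the far end explicitly); bridge locants;
crossed-bond clauses (`<size>/<locant><locant>`); and per-sub-ring
aromaticity flags (`&` aromatic, `T` aliphatic; one flag covers the whole
system; no flag means aromatic — this is what makes `L6J` benzene and
`L6TJ` cyclohexane).

Ring atoms are numbered `A`, `B`, `C`… along the locant path: a single path
visiting every ring atom once (a Hamiltonian path over the ring system)
that starts at the atom with the highest ring-share count.  Assembly follows
the way the notation reads.  Each declared sub-ring, left to right, closes a
cycle of its declared size whose lowest locant is the declared one; the
cycle may walk existing ring bonds, append new atoms at the end of the path,
and contributes exactly one new closure bond (bridged systems additionally
route through off-path bridge atoms, which take the highest locants and must
attach at their declared bridge locant).  This is implemented as a
backtracking search over candidate cycles; a solution must reproduce the
declared system size and exactly the declared multicyclic points, and among
the survivors the assembly minimising the *locant sum* — the summed locant
values shared between pairs of sub-cycles — is chosen.  On fused linear and
angular acenes, perifused systems and the published morphine blocks this
reproduces the standard numbering (e.g. naphthalene's shared atoms at `A`
and `F`); solutions are cached per block declaration.  Post-closure clauses
attach substituents at locants, chain further rings (`- <locant>` plus a new
block), share a spiro atom (`<locant>&- <locant>` plus a new block), pop
back to earlier rings (`&`), and close a pending macrocycle
(`&- <locant><size>J`), whose ring is formed by bonding the open branch back
to the named locant.

Several clause-level syntax details are reconstructed from prose and the two
published morphine spellings rather than from a formal grammar, notably the
multicyclic clause layout, the explicit unsaturation partner, and the macro
return; the morphine equivalence check (both spellings converting to one
canonical SMILES) is the strongest end-to-end evidence the reconstruction is
right.  Heteroatom letters are disambiguated from locants positionally, with
a fallback: a letter that would index past the ring system cannot be a
locant and is read as an element (`PN` on a six-ring is phosphorus then
nitrogen; `KO` on a fifteen-atom system is oxygen at locant `K`).  Inside a
block, a `J` preceded by a space is a locant; otherwise it closes the block.

## Implied conventions and shorthand expansion

Expansion adds what the symbols abbreviate: `V` its carbonyl oxygen, `W` two
double-bonded oxygens on its single neighbour (with nitro nitrogen
charge-separated to N⁺/O⁻ afterwards), and the methyl-filling symbols `X`,
`Y`, `K` top up unused branch slots with methyls (`K` alone is
tetramethylammonium).  Implied double bonding is on by default: two adjacent
`O` symbols with free valence become O=O (so `OO` is molecular oxygen and
the peroxide dianion has no plain spelling — hydrogen peroxide is `QQ`), and
each `C` receives the bond orders needed to reach valence four, preferring
to raise the bond toward the following symbol first (giving `S–C≡N` rather
than S=C=N).  A flag disables the convention, in which case bonds stay
single and unfilled valence becomes implicit hydrogens — disabling it never
increases a bond order.

## Kekulization as maximum matching

WLN's aromaticity is relaxed: a flagged ring is "aromatic" if it carries the
maximum number of double bonds placeable after heteroatom assignment, with
no Hückel condition.  Eligible atoms are aromatic-flagged ring members with
a free valence slot after accounting for charges and guaranteed hydrogens
(`M` = NH is ineligible, pyridine-type `N` is eligible); the maximum
matching over the eligible ring subgraph becomes the double-bond set —
computed by augmenting-path (Hopcroft–Karp) matching when the subgraph is
bipartite and by blossom matching otherwise, via networkx.  Unmatched
eligible atoms keep an implicit hydrogen (one CH₂ survives in phenalene).
Among equal-size maximum matchings any choice is acceptable: rings are
emitted with explicit bond orders and the output toolkit's aromaticity
perception then applies, so canonical SMILES is invariant to the tie-break;
the suite asserts this under randomized matching order.  For odd rings
written with an eligible heteroatom (e.g. `T5NJ`), different maximum
matchings correspond to different tautomers; the deterministic lowest-index
order fixes the choice.

## Output and comparison

The finished graph becomes a connection table — atoms in source order with
formal charges and implicit hydrogen counts (smallest allowed valence at or
above the bond-order sum; hypervalent S and P use their extended valences),
bonds with integer orders, ion components partitioned — and is handed to
RDKit, which performs sanitization and canonical SMILES/InChI emission.
One toolkit canonicalises both converter output and benchmark references,
so string comparison is self-consistent.  References are stripped of
stereochemistry first (WLN carries essentially none).  Failed conversions
are scored with the Tanimoto coefficient over RDKit's path-based
fingerprint, the analogue of the linear-fragment FP2 fingerprint
traditionally used for this drug-like size range: scores near 1 mark
near-misses worth curating.

## Error handling

Faults are reported as `position: message` against the original string;
errors inside a ring block point at the block's closing `J`.  Two repairs
run by default (a strict flag disables both): an over-branched symbol with a
same-element higher-degree counterpart is raised (`M`→`N`, `Q`→`O`) and the
substitution logged, and spaces that make no semantic sense — the classic
OCR artefact, as in `Z2Z & GH` — are skipped with a warning.  There is no
raise target above `N`, so genuine over-branching still fails.

## Bundled data and what the tests show

The two bundled tables are *synthetic*: `synthetic_smith.tsv` holds 69
hand-curated WLN:SMILES pairs in the style of an encoding-manual example set
(linear/branched chains, ions, shorthands, implied bonds, mono- through
multicyclic, bridged, spiro and macrocyclic rings, element codes), and
`synthetic_curation.tsv` adds the artefact classes seen in harvested
databases (OCR spaces, `&&` suffixes, upper-case MANTRAP-style trailers,
lower-case junk).  They exercise every code path and pin the numbers the
acceptance script reports, but they do not reproduce the scale or the error
*distribution* of the real ChEMBL/PubChem/ChemSpider dumps; passing here
shows the machinery is correct on representative constructs, not what
precision it would achieve on a particular database.  The published
four-table benchmark can be scored by dropping the tables under
`data/benchmarks/`.

## Design decisions and limitations

* Locant extension: each trailing `&` advances a locant by 24 (the size of
  the `A`–`X` range); the step size is a design choice fixed by the
  round-trip property.
* The digit `0` is accepted by the matcher but rejected by the parser as a
  zero-length chain; no compound example uses it.
* Explicit charge clauses ("ionic charges, free radicals and isotopes") are
  not implemented: their sub-syntax lives only in the original encoding
  manual, which was not available during development, and guessing it would
  be worse than declining.  `K`'s implied +1 and nitro charge separation are
  supported.
* Chelate blocks (`D`) parse as heterocycles; zero-order coordination
  semantics, metallocenes and catenanes are experimental territory and not
  modelled.  Bridged assembly is validated on classic bicyclics
  (norbornane) but the size-count bookkeeping for exotic bridge patterns is
  heuristic.
* MANTRAP clauses (mixtures, tautomers, polymers, …) are detected as
  unsupported trailers, never interpreted.  Stereochemistry and canonical
  (Rule 2) ordering enforcement are out of scope; non-canonical but
  well-formed strings convert.
* Heteroatom-vs-locant letter ambiguity is resolved heuristically (clause
  shape plus the ring-size bound); pathological blocks that defeat the
  heuristic will mis-place atoms rather than fail loudly.
* The ring-assembly search is exponential in principle; declared system
  sizes and multicyclic points prune it to milliseconds on everything
  tested (≤ 5 rings, ≤ 18 atoms), and results are cached.
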