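"""Relaxed-grammar finite-state matcher for WLN ("wlngrep").

The WLN language proper is context-free (branch counts and ring closures must
balance), so an exact regular description does not exist.  Following the
standard trick for chemical-entity grammars, the matcher recognises a
*relaxed* WLN language -- any number of branches after a given symbol, any
number of closures -- as a finite automaton, and re-imposes the balancing
rules with a pushdown stack at match time:

* an NFA is hand-built from the token-adjacency productions (linear chains,
  branching, ring blocks, locant clauses, element codes, crossed bonds,
  macro/spiro dash clauses);
* the subset construction turns it into a DFA;
* Moore partition refinement yields the minimal DFA (reported for size
  comparisons; matching runs on the annotated subset-construction machine so
  stack actions can be keyed on the grammar context of each state);
* matching runs the DFA with a stack tracking open ring blocks plus counters
  for open branches, so that ring closures never exceed opens.

Exact matching accepts a line only if the whole line is consumed in an
accepting state with every ring block closed.  Greedy matching extracts
non-overlapping leftmost-longest valid substrings from free text; spans of
length one are suppressed by default (most lone capitals are themselves valid
WLN strings, which would light up ordinary prose).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from functools import lru_cache

from .symbols import BRANCHERS, TERMINATORS, WLN_CHARSET

EPSILON = ""

LETTERS = [chr(c) for c in range(ord("A"), ord("Z") + 1)]
DIGITS = list("0123456789")
LOCANT_LETTERS = [c for c in LETTERS if c <= "X"]
RING_OPEN = list("LTD")
#: chain letters with a plain acyclic atom meaning (C and R are special-cased)
CHAIN_LETTERS = list("BEFGHIKMNOPQSVWXYZ")


# ---------------------------------------------------------------------------
# Automaton types
# ---------------------------------------------------------------------------

@dataclass
class NFA:
    """Nondeterministic automaton; transitions may target several states.

    ``EPSILON`` (the empty string) keys spontaneous transitions.
    """

    states: set[str] = field(default_factory=set)
    transitions: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    start: str = "START"
    accepts: set[str] = field(default_factory=set)

    def add(self, src: str, char: str, *dsts: str) -> None:
        self.states.add(src)
        self.states.update(dsts)
        self.transitions.setdefault((src, char), set()).update(dsts)

    def alphabet(self) -> set[str]:
        return {c for (_, c) in self.transitions if c != EPSILON}

    def eclose(self, states: frozenset[str]) -> frozenset[str]:
        out = set(states)
        todo = list(states)
        while todo:
            s = todo.pop()
            for t in self.transitions.get((s, EPSILON), ()):
                if t not in out:
                    out.add(t)
                    todo.append(t)
        return frozenset(out)

    def accepts_string(self, text: str) -> bool:
        cur = self.eclose(frozenset({self.start}))
        for ch in text:
            nxt: set[str] = set()
            for s in cur:
                nxt.update(self.transitions.get((s, ch), ()))
            if not nxt:
                return False
            cur = self.eclose(frozenset(nxt))
        return bool(cur & self.accepts)


@dataclass
class DFA:
    """Deterministic automaton with integer states and partial transitions.

    ``annotations`` maps each state back to the set of NFA state names it was
    built from; the matcher keys its stack actions on these.
    """

    n_states: int
    transitions: dict[tuple[int, str], int]
    start: int
    accepts: set[int]
    annotations: dict[int, frozenset[str]] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.transitions)

    def step(self, state: int, char: str) -> int | None:
        return self.transitions.get((state, char))

    def accepts_string(self, text: str) -> bool:
        s: int | None = self.start
        for ch in text:
            s = self.transitions.get((s, ch))
            if s is None:
                return False
        return s in self.accepts


# ---------------------------------------------------------------------------
# The relaxed WLN grammar as an NFA
# ---------------------------------------------------------------------------

def grammar_nfa() -> NFA:
    """Hand-built NFA for the relaxed WLN token-adjacency language.

    State vocabulary (chain context / ring context / clause context):

    * chain: ``CH_ATOM`` after an atom symbol, ``CH_C`` after the
      full-valence carbon ``C`` (no explicit ``U`` may follow it), ``CH_U`` /
      ``CH_U2`` inside an unsaturation run (at most two ``U``), ``CH_DIGIT``
      inside an alkyl-chain number, ``CH_AMP`` after a branch-closing ``&``;
    * element codes: ``DASH`` ``EC1`` ``EC2`` for ``-XX-`` periodic codes;
    * ring blocks: ``R_BODY`` between the opener and ``J``, ``R_SP`` after a
      space (locants, multicyclic counts, flag groups), ``R_SLASH*`` for
      crossed-bond clauses, ``R_DASH*`` for wide ring sizes ``-nn-``,
      in-ring element codes and embedded (macro) ring openers;
    * post-ring clauses: ``POSTRING`` after ``J``, ``SPACE``/``PR_LOC`` for
      ``<space><locant><branch>`` substituents, ``AMP_CLAUSE`` after a
      space-ampersand (new ion or ring pop), ``DASH_SP``/``LOC_DASH``/
      ``MAC_SIZE`` for ring-chaining, spiro and macro-return dash clauses.

    A terminator symbol is allowed to be *followed* by further symbols here;
    whether that is legal depends on the branch stack and is enforced by the
    matcher, not the finite control.
    """
    n = NFA()

    def chain_targets(c: str) -> tuple[str, ...]:
        if c == "C":
            return ("CH_C",)
        if c == "R":
            # benzene shorthand: behaves as an atom and opens locant clauses
            return ("CH_ATOM", "POSTRING")
        return ("CH_ATOM",)

    def add_chain_moves(src: str, with_u: bool = True) -> None:
        for c in CHAIN_LETTERS + ["C", "R"]:
            n.add(src, c, *chain_targets(c))
        for d in DIGITS:
            n.add(src, d, "CH_DIGIT")
        for c in RING_OPEN:
            n.add(src, c, "R_BODY")
        n.add(src, "-", "DASH")
        if with_u:
            n.add(src, "U", "CH_U")

    # chain context ---------------------------------------------------------
    add_chain_moves("START", with_u=False)   # U needs a parent
    add_chain_moves("CH_ATOM")
    add_chain_moves("CH_C", with_u=False)    # C's unsaturation is implied
    add_chain_moves("CH_DIGIT")
    add_chain_moves("CH_AMP")
    add_chain_moves("CH_U", with_u=False)
    add_chain_moves("CH_U2", with_u=False)
    n.add("CH_U", "U", "CH_U2")              # degree of unsaturation <= 2
    for s in ("CH_ATOM", "CH_C", "CH_DIGIT", "CH_AMP"):
        n.add(s, "&", "CH_AMP")
        n.add(s, " ", "SPACE")

    # space clauses ---------------------------------------------------------
    for c in LOCANT_LETTERS:
        n.add("SPACE", c, "PR_LOC")
    n.add("SPACE", "&", "AMP_CLAUSE")
    n.add("PR_LOC", "&", "PR_LOC")           # locant extension past 'X'
    n.add("PR_LOC", " ", "SPACE")
    add_chain_moves("PR_LOC")
    # after a space-ampersand: a new ion component, or a popped-ring locant
    add_chain_moves("AMP_CLAUSE", with_u=False)
    for c in LOCANT_LETTERS:
        n.add("AMP_CLAUSE", c, "PR_LOC")
    n.add("AMP_CLAUSE", "&", "AMP_CLAUSE")

    # element codes and dash clauses ---------------------------------------
    for c in LETTERS:
        n.add("DASH", c, "EC1")
        n.add("EC1", c, "EC2")
    n.add("EC1", "-", "CH_ATOM")             # single-character hypervalence
    n.add("EC2", "-", "CH_ATOM")
    n.add("DASH", " ", "DASH_SP")            # ring chaining / macro return
    for c in LOCANT_LETTERS:
        n.add("DASH_SP", c, "LOC_DASH")
    n.add("LOC_DASH", "&", "LOC_DASH")
    for c in RING_OPEN:
        n.add("LOC_DASH", c, "R_BODY")       # chained / spiro ring block
    for d in DIGITS:
        n.add("LOC_DASH", d, "MAC_SIZE")     # macro return: locant + size + J
        n.add("MAC_SIZE", d, "MAC_SIZE")
    n.add("MAC_SIZE", "J", "POSTRING")

    # post-ring context -----------------------------------------------------
    n.add("POSTRING", " ", "SPACE")
    n.add("POSTRING", "&", "POSTRING")       # pop back to an earlier ring
    n.add("POSTRING", "-", "DASH")

    # ring blocks -----------------------------------------------------------
    for c in LETTERS:
        if c != "J":
            n.add("R_BODY", c, "R_BODY")
        n.add("R_SP", c, "R_BODY")           # ' J' is a locant, not a closure
        n.add("R_SLASH", c, "R_SLASH2")
        n.add("R_SLASH2", c, "R_BODY")
    for d in DIGITS:
        n.add("R_BODY", d, "R_BODY")
        n.add("R_SP", d, "R_BODY")           # multicyclic point count
        n.add("R_DNUM", d, "R_DNUM")
        n.add("R_DASH", d, "R_DNUM")         # wide ring size -nn-
    n.add("R_BODY", "J", "POSTRING")
    n.add("R_BODY", " ", "R_SP")
    n.add("R_BODY", "&", "R_BODY")           # aromaticity flags
    n.add("R_SP", "&", "R_BODY")
    n.add("R_BODY", "-", "R_DASH")
    n.add("R_SP", "-", "R_DASH")
    n.add("R_BODY", "/", "R_SLASH")
    n.add("R_DNUM", "-", "R_BODY")
    n.add("R_DASH", " ", "R_SP")             # explicit bond-partner clause
    for c in LETTERS:
        if c in RING_OPEN:
            n.add("R_DASH", c, "R_DASH_LTD")
            n.add("R_DASH_LTD", "-", "R_BODY")
            for c2 in LETTERS:
                n.add("R_DASH_LTD", c2, "R_DASH_L2")
            for d in DIGITS:
                n.add("R_DASH_LTD", d, "R_BODY")   # embedded macro opener
        else:
            n.add("R_DASH", c, "R_DASH_L")
    for c in LETTERS:
        n.add("R_DASH_L", c, "R_DASH_L2")
    n.add("R_DASH_L", "-", "R_BODY")
    n.add("R_DASH_L2", "-", "R_BODY")

    n.accepts = {"CH_ATOM", "CH_C", "CH_DIGIT", "CH_AMP", "POSTRING"}
    return n


# ---------------------------------------------------------------------------
# Subset construction and minimization
# ---------------------------------------------------------------------------

def determinize(nfa: NFA) -> DFA:
    """Subset construction; DFA states remember their NFA name sets."""
    alphabet = sorted(nfa.alphabet())
    start = nfa.eclose(frozenset({nfa.start}))
    ids: dict[frozenset[str], int] = {start: 0}
    todo = [start]
    transitions: dict[tuple[int, str], int] = {}
    while todo:
        subset = todo.pop()
        sid = ids[subset]
        for ch in alphabet:
            nxt: set[str] = set()
            for s in subset:
                nxt.update(nfa.transitions.get((s, ch), ()))
            if not nxt:
                continue
            closed = nfa.eclose(frozenset(nxt))
            if closed not in ids:
                ids[closed] = len(ids)
                todo.append(closed)
            transitions[(sid, ch)] = ids[closed]
    accepts = {i for subset, i in ids.items() if subset & nfa.accepts}
    annotations = {i: subset for subset, i in ids.items()}
    return DFA(len(ids), transitions, 0, accepts, annotations)


def minimize(dfa: DFA) -> DFA:
    """Moore partition refinement (with an implicit dead state).

    Unreachable states cannot occur (subset construction only emits reachable
    ones); the result has no pair of states equivalent under the
    Myhill-Nerode relation.
    """
    alphabet = sorted({c for (_, c) in dfa.transitions})
    # class 0 = dead state sentinel (None)
    cls = {s: (1 if s in dfa.accepts else 2) for s in range(dfa.n_states)}
    while True:
        sig: dict[int, tuple] = {}
        for s in range(dfa.n_states):
            row = tuple(
                cls.get(dfa.transitions.get((s, c)), 0) for c in alphabet
            )
            sig[s] = (cls[s], row)
        new_ids: dict[tuple, int] = {}
        new_cls: dict[int, int] = {}
        for s in range(dfa.n_states):
            if sig[s] not in new_ids:
                new_ids[sig[s]] = len(new_ids) + 1
            new_cls[s] = new_ids[sig[s]]
        if len(set(new_cls.values())) == len(set(cls.values())):
            cls = new_cls
            break
        cls = new_cls
    # rebuild with the start state's class first
    order: dict[int, int] = {}

    def mid(c: int) -> int:
        if c not in order:
            order[c] = len(order)
        return order[c]

    mid(cls[dfa.start])
    transitions: dict[tuple[int, str], int] = {}
    accepts: set[int] = set()
    annotations: dict[int, frozenset[str]] = {}
    for s in range(dfa.n_states):
        ms = mid(cls[s])
        annotations[ms] = annotations.get(ms, frozenset()) | dfa.annotations.get(
            s, frozenset()
        )
        if s in dfa.accepts:
            accepts.add(ms)
        for c in alphabet:
            t = dfa.transitions.get((s, c))
            if t is not None:
                transitions[(ms, c)] = mid(cls[t])
    return DFA(len(order), transitions, 0, accepts, annotations)


# ---------------------------------------------------------------------------
# Stack-augmented matching
# ---------------------------------------------------------------------------

@dataclass
class MatchSpan:
    """A matched substring: 0-based, half-open offsets."""

    start: int
    end: int
    text: str


@dataclass
class MatcherConfig:
    mode: str = "greedy"                 # "exact" | "greedy"
    allow_single_letter: bool = False
    strip_suffix: bool = True


@dataclass
class _RunState:
    state: int
    rings_open: int = 0
    rings_closed: int = 0
    branches: int = 0
    terminated: bool = False
    alive: bool = True


_CHAIN_STATES = frozenset(
    {"START", "CH_ATOM", "CH_C", "CH_DIGIT", "CH_AMP", "CH_U", "CH_U2"}
)
_RING_STATES = frozenset(
    {"R_BODY", "R_SP", "R_SLASH", "R_SLASH2", "R_DASH", "R_DASH_L",
     "R_DASH_LTD", "R_DASH_L2", "R_DNUM"}
)


class Matcher:
    """The relaxed-WLN DFA plus its companion stack discipline."""

    def __init__(self) -> None:
        self.nfa = grammar_nfa()
        self.dfa = determinize(self.nfa)
        self.min_dfa = minimize(self.dfa)
        self._ann = self.dfa.annotations

    # -- single-character step ---------------------------------------------
    def start_state(self) -> _RunState:
        return _RunState(self.dfa.start)

    def step(self, rs: _RunState, ch: str) -> _RunState:
        if not rs.alive:
            return rs
        src = self._ann[rs.state]
        nxt = self.dfa.step(rs.state, ch)
        if nxt is None:
            return replace(rs, alive=False)
        dst = self._ann[nxt]
        rs = replace(rs, state=nxt)
        src_ring = bool(src & _RING_STATES)
        src_chain_only = src <= _CHAIN_STATES and "START" not in src

        # a fresh clause (space / locant / ampersand / ring close) resets the
        # chain-termination latch
        if src & {"SPACE", "PR_LOC", "AMP_CLAUSE", "POSTRING", "LOC_DASH"}:
            rs.terminated = False

        if rs.terminated and src_chain_only and ch not in " &":
            return replace(rs, alive=False)

        # ring open / close bookkeeping
        if ch in "LTD" and not src_ring and "R_BODY" in dst:
            rs.rings_open += 1
        elif "R_DASH_LTD" in src and ch.isdigit() and "R_BODY" in dst:
            rs.rings_open += 1           # embedded (macro) ring opener
        elif ch == "J" and "POSTRING" in dst and ("MAC_SIZE" in src or src_ring):
            if rs.rings_open == 0:
                return replace(rs, alive=False)
            rs.rings_open -= 1
            rs.rings_closed += 1
            rs.terminated = False
        elif ch == "R" and not src_ring and "POSTRING" in dst:
            rs.rings_closed += 1         # benzene shorthand takes locants

        if src_ring:
            return rs

        # locant clauses require a ring (or benzene) in the component
        if "SPACE" in src and ch.isalpha() and dst == {"PR_LOC"}:
            if rs.rings_closed == 0:
                return replace(rs, alive=False)

        if "SPACE" in src and ch == "&":
            # ring pop when rings are open to pop, else a new ion component
            if rs.rings_closed > 0:
                rs.rings_closed -= 1
            else:
                rs.branches = 0
                rs.terminated = False
        elif "POSTRING" in src and ch == "&":
            rs.rings_closed = max(0, rs.rings_closed - 1)
        elif ch == "&" and src_chain_only:
            rs.branches = max(0, rs.branches - 1)
        elif ch in BRANCHERS and (dst & {"CH_ATOM", "CH_C"}):
            rs.branches += 1
        elif (
            ch in TERMINATORS
            and (dst & {"CH_ATOM", "CH_C"})
            and not (src & {"START", "AMP_CLAUSE"})
            and rs.branches == 0
        ):
            rs.terminated = True
        return rs

    def accepting(self, rs: _RunState) -> bool:
        return rs.alive and rs.state in self.dfa.accepts and rs.rings_open == 0

    # -- public matching API -----------------------------------------------
    def run(self, text: str) -> _RunState:
        rs = self.start_state()
        for ch in text:
            rs = self.step(rs, ch)
            if not rs.alive:
                break
        return rs

    def match_exact(self, line: str) -> bool:
        if not line:
            return False
        return self.accepting(self.run(line))

    def match_greedy(self, text: str, cfg: MatcherConfig | None = None) -> list[MatchSpan]:
        cfg = cfg or MatcherConfig()
        min_len = 1 if cfg.allow_single_letter else 2
        spans: list[MatchSpan] = []
        i, n = 0, len(text)
        while i < n:
            ch = text[i]
            if ch not in WLN_CHARSET or ch == " ":
                i += 1
                continue
            rs = self.start_state()
            best = -1
            for j in range(i, n):
                rs = self.step(rs, text[j])
                if not rs.alive:
                    break
                if self.accepting(rs):
                    best = j + 1
            if best - i >= min_len:
                spans.append(MatchSpan(i, best, text[i:best]))
                i = best
            else:
                i += 1
        return spans

    def ring_depth_at(self, line: str, index: int) -> int:
        """Open ring blocks after consuming ``line[:index]`` (0 if unknown)."""
        rs = self.start_state()
        for ch in line[:index]:
            rs = self.step(rs, ch)
            if not rs.alive:
                return 0
        return rs.rings_open


@lru_cache(maxsize=1)
def build_matcher() -> Matcher:
    """The shared matcher instance (construction is deterministic)."""
    return Matcher()


def match_exact(line: str) -> bool:
    """True iff the whole line is a syntactically valid (relaxed) WLN string."""
    return build_matcher().match_exact(line)


def match_greedy(text: str, cfg: MatcherConfig | None = None) -> list[MatchSpan]:
    """Leftmost-longest non-overlapping valid WLN substrings of ``text``."""
    return build_matcher().match_greedy(text, cfg)


def strip_annotation_suffix(line: str) -> tuple[str, str]:
    """Split a historical ``&&`` annotation suffix off a WLN string.

    The split happens at the first ``" &&"`` occurring outside any ring
    block; the suffix (which may be mixed case, e.g. ``&&Alpha``) is returned
    separately.  Lines without such a suffix come back unchanged.
    """
    m = build_matcher()
    pos = 0
    while True:
        idx = line.find(" &&", pos)
        if idx < 0:
            return line, ""
        if m.ring_depth_at(line, idx) == 0:
            return line[:idx], line[idx + 3:]
        pos = idx + 1


# ---------------------------------------------------------------------------
# Grammar-driven sampling (used by the language-agreement checks)
# ---------------------------------------------------------------------------

def sample_strings(n: int, seed: int, max_len: int = 60) -> list[str]:
    """Random strings drawn by walking the grammar NFA.

    Walks stop preferentially in accepting states, so most samples are
    accepted by the finite control; a fraction is mutated afterwards to
    produce near-miss negatives.  This exercises the automata pipeline, not
    chemistry.
    """
    rng = random.Random(seed)
    nfa = grammar_nfa()
    moves: dict[str, list[tuple[str, str]]] = {}
    for (src, ch), dsts in nfa.transitions.items():
        for d in dsts:
            moves.setdefault(src, []).append((ch, d))
    alphabet = sorted(nfa.alphabet())
    out: list[str] = []
    while len(out) < n:
        state, chars = nfa.start, []
        for _ in range(max_len):
            if state in nfa.accepts and chars and rng.random() < 0.2:
                break
            options = moves.get(state)
            if not options:
                break
            ch, state = rng.choice(options)
            chars.append(ch)
        s = "".join(chars)
        if not s:
            continue
        if rng.random() < 0.3:  # mutate into a probable negative
            k = rng.randrange(len(s))
            s = s[:k] + rng.choice(alphabet) + s[k + 1:]
        out.append(s)
    return out
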