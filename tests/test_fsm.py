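"""The relaxed-grammar matcher: automata pipeline and matching semantics."""

import random

import pytest

from wlnkit.fsm import (MatcherConfig, build_matcher, determinize,
                        grammar_nfa, match_exact, match_greedy, minimize,
                        sample_strings, strip_annotation_suffix)

MORPHINE_MACRO = "T-T665 B6 2AB O KO NUT &TTJ IQ MQ B2N1 &- D6J"
MORPHINE_ALT = "T B65 H6 F6 F6 3FGH R AO DU GX PN HU- MTT &TTJ CQ JQ P1"


@pytest.mark.parametrize("line,accepted", [
    ("L C666J", True),                  # anthracene
    ("Q1XGG2Y1Q1Z", True),
    ("SCN", True),
    (MORPHINE_MACRO, True),
    (MORPHINE_ALT, True),
    ("L F6 E6 B666 CV DUTJ A1 HVQ H1 K1 N1 O1 S1 S1 TQ", True),
    ("Z2Z &GH", True),
    ("Z2Z & GH", False),                # space after the ion '&' is invalid
    ("SCUUN", False),                   # explicit U after C is disallowed
    ("", False),
    ("Z2ZG", False),                    # symbol after a terminated chain
    ("1U", False),                      # U needs a child
    ("GH", True),
    ("L6J A1", True),
    ("A", False),                       # 'A' is a locant, not a compound
    ("J", False),
    ("Q&&beta", False),                 # suffix must be stripped first
])
def test_match_exact(line, accepted):
    assert match_exact(line) is accepted


def test_greedy_extracts_leftmost_longest():
    spans = match_greedy("prepared Q1XGG2Y1Q1Z in two steps")
    assert [s.text for s in spans] == ["Q1XGG2Y1Q1Z"]
    span = spans[0]
    assert "prepared Q1XGG2Y1Q1Z in two steps"[span.start:span.end] == span.text


def test_single_letter_suppression_flag():
    assert match_greedy("E") == []
    spans = match_greedy("E", MatcherConfig(allow_single_letter=True))
    assert [s.text for s in spans] == ["E"]
    # lone letters that are not molecules stay unmatched either way
    assert match_greedy("A", MatcherConfig(allow_single_letter=True)) == []


def test_greedy_agrees_with_all_substrings_oracle(matcher):
    """Leftmost-longest extraction equals the naive O(n^2) oracle."""
    rng = random.Random(20240915)
    alphabet = "QXZGEY12 NOVRLTJ&U-abcdef ,."

    def oracle(text):
        spans, i = [], 0
        while i < len(text):
            best = -1
            for j in range(len(text), i, -1):
                if match_exact(text[i:j]):
                    best = j
                    break
            if best - i >= 2:
                spans.append((i, best, text[i:best]))
                i = best
            else:
                i += 1
        return spans

    for _ in range(8):
        text = "".join(rng.choice(alphabet) for _ in range(120))
        got = [(s.start, s.end, s.text) for s in match_greedy(text)]
        assert got == oracle(text)


def test_nfa_dfa_minimal_dfa_language_agreement(matcher):
    nfa = grammar_nfa()
    dfa = matcher.dfa
    mdfa = matcher.min_dfa
    for s in sample_strings(10_000, seed=7):
        a = nfa.accepts_string(s)
        assert dfa.accepts_string(s) is a
        assert mdfa.accepts_string(s) is a


def test_minimized_machine_has_no_equivalent_state_pair(matcher):
    """Re-minimizing the minimal machine must not merge anything further."""
    mdfa = matcher.min_dfa
    again = minimize(mdfa)
    assert again.n_states == mdfa.n_states
    # pairwise distinguishability via partition refinement signatures
    alphabet = sorted({c for (_, c) in mdfa.transitions})
    cls = {s: (s in mdfa.accepts) for s in range(mdfa.n_states)}
    while True:
        sig = {s: (cls[s], tuple(cls.get(mdfa.transitions.get((s, c)), None)
                                 for c in alphabet))
               for s in range(mdfa.n_states)}
        groups = {}
        for s, v in sig.items():
            groups.setdefault(v, []).append(s)
        new_cls = {s: i for i, (_, members) in enumerate(sorted(
            groups.items(), key=str)) for s in members}
        if len(set(new_cls.values())) == len(set(cls.values())):
            break
        cls = new_cls
    assert len(set(cls.values())) == mdfa.n_states


def test_determinization_is_deterministic(matcher):
    dfa = determinize(grammar_nfa())
    for (s, c), t in dfa.transitions.items():
        assert isinstance(t, int)
    assert dfa.n_states == matcher.dfa.n_states
    assert dfa.n_edges == matcher.dfa.n_edges


def test_parser_accepted_strings_are_matcher_accepted(smith_pairs):
    """Relaxation can only widen the language (superset property)."""
    from wlnkit.parser import parse

    for wln, _ in smith_pairs:
        parse(wln)                      # must not raise
        assert match_exact(wln), wln


@pytest.mark.parametrize("line,wln,suffix", [
    ("L F6 E6 B666 CV DUTJ A1 HVQ H1 K1 N1 O1 S1 S1 TQ &&Alpha",
     "L F6 E6 B666 CV DUTJ A1 HVQ H1 K1 N1 O1 S1 S1 TQ", "Alpha"),
    ("SCN", "SCN", ""),
    ("Q &&beta form", "Q", "beta form"),
])
def test_strip_annotation_suffix(line, wln, suffix):
    got_wln, got_suffix = strip_annotation_suffix(line)
    assert (got_wln, got_suffix) == (wln, suffix)
    if wln and " &&" not in wln:
        assert match_exact(got_wln)


def test_machine_size_is_recorded(matcher):
    # informational: the reference machine printed 59 states / 1028 edges;
    # the relaxation boundary is under-specified so only the order of
    # magnitude is comparable
    assert 10 < matcher.min_dfa.n_states < 200
    assert 100 < matcher.min_dfa.n_edges < 5000
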