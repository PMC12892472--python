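"""Capped greedy fuzzy multiset matching: examples, invariants, oracle bounds."""

from __future__ import annotations

from collections import Counter
from itertools import permutations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extracteval.normalization import TokenMultiset
from extracteval.term_matching import (
    MatchPolicy,
    eligible,
    match_multisets,
)

TOKEN = st.text(alphabet="abcdef", min_size=1, max_size=6)
MULTISET = st.dictionaries(TOKEN, st.integers(min_value=1, max_value=3), max_size=4)


def ms(d: dict) -> TokenMultiset:
    return TokenMultiset(dict(d))


class TestExamples:
    def test_overlapping_method_cells(self):
        out = match_multisets(
            ms({"soil": 1, "sampl": 2, "invertebr": 1}),
            ms({"soil": 1, "sampl": 1, "invertebr": 1}),
        )
        assert out.tp == 3
        assert dict(out.fn_tokens) == {"sampl": 1}
        assert not out.fp_tokens

    def test_duplicates_above_manual_cap_are_fp(self):
        out = match_multisets(ms({"marsh": 1}), ms({"marsh": 3}))
        assert out.tp == 1
        assert dict(out.fp_tokens) == {"marsh": 2}

    def test_both_none_reported_is_single_tn(self):
        out = match_multisets(ms({}), ms({}), both_none_reported=True)
        assert out.tn_flag and out.tp == out.fp == out.fn == 0
        assert out.tn == 1

    def test_one_sided_cell_is_all_fn_or_fp(self):
        out = match_multisets(ms({"marsh": 2}), ms({}), both_none_reported=False)
        assert out.tp == 0 and dict(out.fn_tokens) == {"marsh": 2}
        out = match_multisets(ms({}), ms({"marsh": 2}), both_none_reported=False)
        assert out.tp == 0 and dict(out.fp_tokens) == {"marsh": 2}

    def test_fuzzy_same_prefix_match(self):
        # spartina/spartine: similarity 0.95, shared prefix, inside 0.15
        out = match_multisets(ms({"spartina": 1}), ms({"spartine": 1}))
        assert out.tp == 1
        assert out.matched_pairs[0][2] == pytest.approx(0.95)

    def test_exact_matches_take_precedence_over_fuzzy(self):
        # "spartina" should pair with its exact copy, leaving the near-miss
        # to pair fuzzily rather than stealing the exact partner
        out = match_multisets(
            ms({"spartina": 1, "spartine": 1}),
            ms({"spartina": 1, "spartine": 1}),
        )
        assert out.tp == 2
        assert {(m, a) for m, a, _ in out.matched_pairs} == {
            ("spartina", "spartina"),
            ("spartine", "spartine"),
        }


@settings(derandomize=True, max_examples=300)
@given(MULTISET, MULTISET)
def test_conservation(manual, auto):
    out = match_multisets(ms(manual), ms(auto))
    assert out.tp + out.fn == sum(manual.values())
    assert out.tp + out.fp == sum(auto.values())


@settings(derandomize=True, max_examples=300)
@given(MULTISET, MULTISET)
def test_swap_symmetry(manual, auto):
    fwd = match_multisets(ms(manual), ms(auto))
    rev = match_multisets(ms(auto), ms(manual))
    assert fwd.tp == rev.tp
    assert dict(fwd.fp_tokens) == dict(rev.fn_tokens)
    assert dict(fwd.fn_tokens) == dict(rev.fp_tokens)


@settings(derandomize=True, max_examples=300)
@given(MULTISET, MULTISET)
def test_manual_cap_respected(manual, auto):
    out = match_multisets(ms(manual), ms(auto))
    used = Counter(m for m, _, _ in out.matched_pairs)
    for tok, n in used.items():
        assert n <= manual[tok]


@settings(derandomize=True, max_examples=200)
@given(MULTISET, MULTISET)
def test_exact_only_closed_form(manual, auto):
    """With fuzziness disabled, tp is the multiset intersection size."""
    strict = MatchPolicy(same_prefix_max_distance=0.0, diff_prefix_max_distance=0.0)
    out = match_multisets(ms(manual), ms(auto), strict)
    expected = sum(min(n, auto.get(t, 0)) for t, n in manual.items())
    assert out.tp == expected


def _brute_force_max_tp(manual: dict, auto: dict, policy: MatchPolicy) -> int:
    """Maximum-cardinality matching by exhaustive assignment over instances."""
    m_items = [t for t, n in sorted(manual.items()) for _ in range(n)]
    a_items = [t for t, n in sorted(auto.items()) for _ in range(n)]
    if len(m_items) > len(a_items):
        m_items, a_items = a_items, m_items
    best = 0
    for perm in permutations(range(len(a_items)), len(m_items)):
        tp = sum(
            1
            for mi, ai in enumerate(perm)
            if m_items[mi] == a_items[ai] or eligible(m_items[mi], a_items[ai], policy)
        )
        best = max(best, tp)
    return best


SMALL_MULTISET = st.dictionaries(
    st.text(alphabet="abc", min_size=1, max_size=4),
    st.integers(min_value=1, max_value=2),
    max_size=3,
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(SMALL_MULTISET, SMALL_MULTISET)
def test_greedy_never_beats_brute_force(manual, auto):
    """Greedy tp is bounded by the optimal assignment; equal when the
    eligibility graph decomposes into cliques (e.g. exact-only components)."""
    policy = MatchPolicy()
    if sum(manual.values()) > 6 or sum(auto.values()) > 6:
        return
    out = match_multisets(ms(manual), ms(auto), policy)
    optimum = _brute_force_max_tp(manual, auto, policy)
    assert out.tp <= optimum
    tokens = sorted(set(manual) | set(auto))
    is_clique_union = all(
        not (eligible(a, b) and any(
            eligible(a, c) != eligible(b, c) for c in tokens if c not in (a, b)
        ))
        for a in tokens
        for b in tokens
        if a < b
    )
    if is_clique_union:
        assert out.tp == optimum


@settings(derandomize=True, max_examples=60, deadline=None)
@given(SMALL_MULTISET, SMALL_MULTISET)
def test_relaxing_thresholds_never_decreases_tp(manual, auto):
    tight = MatchPolicy(same_prefix_max_distance=0.10, diff_prefix_max_distance=0.02)
    loose = MatchPolicy(same_prefix_max_distance=0.30, diff_prefix_max_distance=0.10)
    tp_tight = match_multisets(ms(manual), ms(auto), tight).tp
    tp_loose = match_multisets(ms(manual), ms(auto), loose).tp
    assert tp_loose >= tp_tight


def test_outcome_accounting_identities():
    out = match_multisets(ms({"aaa": 2, "bbb": 1}), ms({"aaa": 1, "ccc": 2}))
    assert out.tp == len(out.matched_pairs)
    assert out.tp + out.fn == 3
    assert out.tp + out.fp == 3
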