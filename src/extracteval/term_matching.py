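"""Capped, prefix-conditioned fuzzy multiset matching.

Two token multisets — the human baseline ("manual") and the automated
extraction — are matched token instance by token instance.  A candidate
token pair is *eligible* when its Jaro-Winkler distance is at most 0.15
(85% similarity) if the two tokens share their first three characters, or
at most 0.05 (95% similarity) otherwise; sharing a prefix both loosens the
threshold and raises the pair's matching priority.

Matching is greedy and deterministic: exact string matches first, then
same-prefix eligible pairs by descending similarity, then different-prefix
eligible pairs by descending similarity.  The number of matches consuming a
manual token is capped at that token's multiplicity in the manual multiset,
so automated duplicates above the cap become false positives.  Every matched
pair is one true positive; leftover automated instances are false positives
and leftover manual instances false negatives.  A cell where both sides
reported nothing is a single true negative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._jarowinkler import jaro_winkler_similarity as _jw
from .normalization import TokenMultiset

__all__ = [
    "MatchPolicy",
    "MatchOutcome",
    "jaro_winkler_similarity",
    "eligible",
    "shares_prefix",
    "match_multisets",
]


@dataclass(frozen=True)
class MatchPolicy:
    """Thresholds and parameters of the fuzzy matcher.

    Distances are ``1 - similarity``; defaults are the study configuration:
    0.15 for same-prefix pairs, 0.05 otherwise, a three-character prefix,
    and the standard Winkler boost (weight 0.1, up to 4 prefix characters).
    """

    same_prefix_max_distance: float = 0.15
    diff_prefix_max_distance: float = 0.05
    prefix_length: int = 3
    winkler_prefix_weight: float = 0.1
    winkler_max_prefix: int = 4

    def __post_init__(self) -> None:
        for name in ("same_prefix_max_distance", "diff_prefix_max_distance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.same_prefix_max_distance < self.diff_prefix_max_distance:
            raise ValueError(
                "same-prefix threshold must be at least as loose as the "
                "different-prefix threshold"
            )
        if self.prefix_length < 1:
            raise ValueError("prefix_length must be >= 1")


@dataclass(frozen=True)
class MatchOutcome:
    """Token-level confusion outcome for one article-attribute cell."""

    matched_pairs: tuple[tuple[str, str, float], ...]
    fp_tokens: Counter
    fn_tokens: Counter
    tn_flag: bool = False

    @property
    def tp(self) -> int:
        return len(self.matched_pairs)

    @property
    def fp(self) -> int:
        return sum(self.fp_tokens.values())

    @property
    def fn(self) -> int:
        return sum(self.fn_tokens.values())

    @property
    def tn(self) -> int:
        return 1 if self.tn_flag else 0


def jaro_winkler_similarity(a: str, b: str, policy: MatchPolicy = MatchPolicy()) -> float:
    """Jaro-Winkler similarity under the policy's Winkler parameters."""
    return _jw(a, b, policy.winkler_prefix_weight, policy.winkler_max_prefix)


def shares_prefix(a: str, b: str, policy: MatchPolicy = MatchPolicy()) -> bool:
    """True when the first ``prefix_length`` characters agree.

    Tokens shorter than the prefix length compare over their common length.
    """
    k = min(policy.prefix_length, len(a), len(b))
    return a[:k] == b[:k]


#: guard against float representation error at the threshold boundaries
#: (e.g. a pair whose similarity is exactly 0.95 in real arithmetic)
_EPS = 1e-12


def eligible(a: str, b: str, policy: MatchPolicy = MatchPolicy()) -> bool:
    """Whether a token pair may be matched under the two-tier threshold."""
    distance = 1.0 - jaro_winkler_similarity(a, b, policy)
    if shares_prefix(a, b, policy):
        return distance <= policy.same_prefix_max_distance + _EPS
    return distance <= policy.diff_prefix_max_distance + _EPS


def match_multisets(
    manual: TokenMultiset,
    auto: TokenMultiset,
    policy: MatchPolicy = MatchPolicy(),
    *,
    both_none_reported: bool | None = None,
) -> MatchOutcome:
    """Greedy capped matching of an automated multiset against the manual one.

    ``both_none_reported`` marks the true-negative case; when left as None it
    is inferred from both multisets being empty (an explicitly empty pair of
    cells is exactly what "none reported" produces downstream).
    """
    if both_none_reported is None:
        both_none_reported = manual.total == 0 and auto.total == 0
    if both_none_reported and (manual.total or auto.total):
        raise ValueError("both_none_reported set but a multiset is non-empty")

    remaining_m = Counter(manual.counts)
    remaining_a = Counter(auto.counts)

    # Rank candidate pairs: exact matches, then same-prefix eligible pairs by
    # descending similarity, then different-prefix eligible pairs.  Ties are
    # broken on the unordered token pair so that swapping the inputs replays
    # the same decisions mirrored (keeps the matcher swap-symmetric).
    candidates: list[tuple[int, float, tuple[str, str], str, str]] = []
    for m_tok in remaining_m:
        for a_tok in remaining_a:
            if m_tok == a_tok:
                candidates.append((0, -1.0, (m_tok, a_tok), m_tok, a_tok))
                continue
            sim = jaro_winkler_similarity(m_tok, a_tok, policy)
            distance = 1.0 - sim
            if shares_prefix(m_tok, a_tok, policy):
                if distance <= policy.same_prefix_max_distance + _EPS:
                    candidates.append((1, -sim, _unordered(m_tok, a_tok), m_tok, a_tok))
            elif distance <= policy.diff_prefix_max_distance + _EPS:
                candidates.append((2, -sim, _unordered(m_tok, a_tok), m_tok, a_tok))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    matched: list[tuple[str, str, float]] = []
    for tier, neg_sim, _key, m_tok, a_tok in candidates:
        n = min(remaining_m[m_tok], remaining_a[a_tok])
        if n <= 0:
            continue
        sim = 1.0 if tier == 0 else -neg_sim
        matched.extend([(m_tok, a_tok, sim)] * n)
        remaining_m[m_tok] -= n
        remaining_a[a_tok] -= n

    fn = Counter({t: c for t, c in remaining_m.items() if c > 0})
    fp = Counter({t: c for t, c in remaining_a.items() if c > 0})
    return MatchOutcome(
        matched_pairs=tuple(matched),
        fp_tokens=fp,
        fn_tokens=fn,
        tn_flag=both_none_reported,
    )


def _unordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)
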