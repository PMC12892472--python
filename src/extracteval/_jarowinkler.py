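"""Jaro and Jaro-Winkler string similarity.

Self-contained implementation of the classic record-linkage similarity:
the Jaro similarity counts characters matching within a sliding window of
``floor(max(|a|,|b|)/2) - 1`` positions and discounts transpositions; the
Winkler variant boosts pairs sharing a common prefix (up to 4 characters,
weight 0.1 by default).  Distance is ``1 - similarity`` throughout the
package.
"""

from __future__ import annotations

__all__ = ["jaro_similarity", "jaro_winkler_similarity"]


def jaro_similarity(a: str, b: str) -> float:
    """Jaro similarity in [0, 1]. Symmetric; 1.0 iff the strings are equal."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    a_matched = [False] * la
    b_matched = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_matched[j] and b[j] == ca:
                a_matched[i] = True
                b_matched[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # half-transpositions: matched characters out of mutual order
    b_seq = [b[j] for j in range(lb) if b_matched[j]]
    t = sum(ca != cb for ca, cb in zip((a[i] for i in range(la) if a_matched[i]), b_seq))
    t //= 2
    return (m / la + m / lb + (m - t) / m) / 3.0


def jaro_winkler_similarity(
    a: str,
    b: str,
    prefix_weight: float = 0.1,
    max_prefix: int = 4,
) -> float:
    """Jaro similarity with the Winkler common-prefix boost.

    ``sim = jaro + L * prefix_weight * (1 - jaro)`` where ``L`` is the length
    of the common prefix capped at ``max_prefix``.  No boost threshold is
    applied (the boost acts at every similarity level).
    """
    if not a or not b:
        raise ValueError("jaro_winkler_similarity requires non-empty strings")
    sim = jaro_similarity(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= max_prefix:
            break
        prefix += 1
    return sim + prefix * prefix_weight * (1.0 - sim)
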