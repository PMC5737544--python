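"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (full enumeration, literal rule
translation) and shares no code with the package internals it checks.
"""

from itertools import combinations
from math import comb
from typing import List, Optional, Tuple

import numpy as np


def exact_mw_two_sided(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Assumes no ties.  The U statistic of group x is the number of (xi, yj)
    pairs with xi > yj; the null distribution is built by enumerating every
    C(n1+n2, n1) placement of the x-ranks, and the two-sided p-value is
    twice the smaller tail probability at the observed U, capped at 1.
    """
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i for i, v in enumerate(pooled)}
    obs_u = sum(1 for xi in x for yj in y if xi > yj)

    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    for subset in combinations(range(n1 + n2), n1):
        # U for a given placement of x-ranks among the pooled order
        u = sum(r - k for k, r in enumerate(sorted(subset)))
        counts[u] += 1
    total = comb(n1 + n2, n1)
    cdf_le = counts[: obs_u + 1].sum() / total
    cdf_ge = counts[obs_u:].sum() / total
    return min(1.0, 2.0 * min(cdf_le, cdf_ge))


def predict_fragment_call(
    allele: Optional[Tuple[int, int]],
    frag_start: int,
    insert_len: int,
    read_length: int = 150,
    edge: int = 8,
    min_len: int = 3,
    max_len: int = 29,
) -> Tuple[str, Optional[Tuple[int, int]], Optional[str]]:
    """Predict the pipeline's fragment classification from simulator truth.

    Pure geometry: the deletion junction sits at allele coordinate ``s``
    (the deletion start); a mate covering allele interval [a, a+L) shows the
    junction iff a < s < a+L, with read offsets (s-a, L-(s-a)).  The
    read-level filter rules and mate reconciliation are re-stated literally.

    Returns (status, call_key, reason).
    """
    if allele is None:
        return "reference", None, None
    s, length = allele

    def mate(a: int):
        if a < s < a + read_length:
            left = s - a
            right = read_length - left
            if length < min_len:
                return ("reference", None, None)
            if left < edge or right < edge:
                return ("discarded", None, "edge-proximal")
            if length > max_len:
                return ("discarded", None, "length-ge-30")
            return ("deletion", (s, length), None)
        return ("reference", None, None)

    m1 = mate(frag_start)
    m2 = mate(frag_start + insert_len - read_length)
    for status, key, reason in (m1, m2):
        if status == "discarded":
            return "discarded", None, reason
    dels = [m for m in (m1, m2) if m[0] == "deletion"]
    if dels:
        return "deletion", dels[0][1], None
    return "reference", None, None


def count_deletions_at(dels: List, position: int) -> int:
    """Brute-force interval scan for the per-position deletion count."""
    return sum(
        1 for d in dels if position in range(d.start, d.start + d.length)
    )
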