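"""Shared statistical primitives: Mann-Whitney test and bootstrap median CI."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

#: largest min(n1, n2) for which the exact Mann-Whitney null is used
EXACT_MAX_N = 8


def mann_whitney_two_sided(
    x: Sequence[float], y: Sequence[float], exact_max: int = EXACT_MAX_N
) -> float:
    """Two-sided Mann-Whitney U test p-value.

    Per-position groups can be tiny, where the normal approximation is poor,
    so the exact null distribution is used whenever ``min(n1, n2) <= 8`` and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections applies.  Identical groups return p = 1 (capped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def bootstrap_median_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[float, float, float]:
    """Median and percentile-bootstrap confidence interval.

    Resamples the values with replacement (same size) ``n_boot`` times and
    takes the (1-level)/2 and 1-(1-level)/2 percentiles of the resample
    medians.  Reproducible via ``seed`` or an explicit generator.

    Returns
    -------
    (median, ci_low, ci_high)
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    if rng is None:
        rng = np.random.default_rng(seed)
    median = float(np.median(values))
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return median, float(lo), float(hi)
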