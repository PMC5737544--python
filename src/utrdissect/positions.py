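"""Per-nucleotide regulatory-activity map.

For every reference position, the set of retained distinct deletions whose
deleted interval contains that position ("involving" the position) yields a
distribution of count ratios r.  The map reports, per position:

* n, the number of distinct deletions involving the position (positions with
  fewer than 4 are not analyzed);
* the median r (and median normalized r) with a percentile-bootstrap 95%
  confidence interval, resampling distinct deletions — the exchangeable unit
  of r — rather than reads;
* a two-sided Mann-Whitney p-value comparing r at the position against r of
  all other retained distinct deletions, Bonferroni-corrected over the
  family of positions actually analyzed (tests never performed are not part
  of the family).

Two-sided testing is used throughout because deletions can both increase
(destabilizing-element removal) and decrease (transcription-element removal)
expression.  Runs of adjacent significant positions merge into intervals
(BED-compatible half-open coordinates).
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import Interval
from .quantify import DistinctDeletion
from .stats import bootstrap_median_ci, mann_whitney_two_sided

MIN_DELETIONS_PER_POSITION = 4

# re-exported here as the position-level test of the map
position_test = mann_whitney_two_sided


@dataclasses.dataclass
class PositionStat:
    """Activity statistics for one reference position."""

    position: int
    n_deletions: int
    analyzed: bool
    median_r: Optional[float] = None
    median_normalized_r: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    p_bonferroni: Optional[float] = None
    significant: bool = False


def deletions_at(
    dels: Sequence[DistinctDeletion], position: int
) -> List[DistinctDeletion]:
    """Distinct deletions whose deleted interval [start, start+length) contains ``position``."""
    return [d for d in dels if d.start <= position < d.start + d.length]


def build_map(
    dels: Sequence[DistinctDeletion],
    ref_length: int,
    reference_ratio: float,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    min_deletions: int = MIN_DELETIONS_PER_POSITION,
    compute_ci: bool = True,
) -> Tuple[List[PositionStat], List[Interval]]:
    """Build the per-position activity map over ``[0, ref_length)``.

    ``dels`` must be the retained distinct deletions with r computed.
    Returns the per-position statistics and the merged intervals of
    Bonferroni-significant positions.  Fully deterministic given
    (inputs, seed).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    retained = [d for d in dels if d.retained and d.r is not None]
    r_all = np.array([d.r for d in retained])
    rng = np.random.default_rng(seed)

    # index: position -> indices of deletions involving it
    index: List[List[int]] = [[] for _ in range(ref_length)]
    for i, d in enumerate(retained):
        for pos in range(d.start, min(d.start + d.length, ref_length)):
            index[pos].append(i)

    stats: List[PositionStat] = []
    analyzed_positions: List[int] = []
    for pos in range(ref_length):
        idx = index[pos]
        n = len(idx)
        if n < min_deletions or n == len(retained):
            # too few deletions, or no "elsewhere" group to compare against
            stats.append(PositionStat(position=pos, n_deletions=n, analyzed=False))
            continue
        at = r_all[idx]
        mask = np.ones(len(retained), dtype=bool)
        mask[idx] = False
        elsewhere = r_all[mask]
        if compute_ci:
            median, lo, hi = bootstrap_median_ci(at, n_boot=n_boot, rng=rng)
        else:
            median, lo, hi = float(np.median(at)), None, None
        p = mann_whitney_two_sided(at, elsewhere)
        stats.append(
            PositionStat(
                position=pos,
                n_deletions=n,
                analyzed=True,
                median_r=median,
                median_normalized_r=median / reference_ratio,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
            )
        )
        analyzed_positions.append(pos)

    m = len(analyzed_positions)
    for st in stats:
        if st.analyzed:
            st.p_bonferroni = min(1.0, st.p_value * m)
            st.significant = st.p_bonferroni <= alpha
    return stats, merge_significant(stats)


def merge_significant(stats: Sequence[PositionStat]) -> List[Interval]:
    """Merge runs of adjacent significant positions into half-open intervals."""
    intervals: List[Interval] = []
    start = None
    prev = None
    for st in stats:
        if st.significant:
            if start is None:
                start = st.position
            elif st.position != prev + 1:
                intervals.append(Interval(start, prev + 1))
                start = st.position
            prev = st.position
    if start is not None:
        intervals.append(Interval(start, prev + 1))
    return intervals


def map_to_frame(stats: Sequence[PositionStat]) -> pd.DataFrame:
    """Per-position TSV-ready table."""
    return pd.DataFrame(
        {
            "position": [s.position for s in stats],
            "n_deletions": [s.n_deletions for s in stats],
            "analyzed": [s.analyzed for s in stats],
            "median_r": [_na(s.median_r) for s in stats],
            "median_normalized_r": [_na(s.median_normalized_r) for s in stats],
            "ci_low": [_na(s.ci_low) for s in stats],
            "ci_high": [_na(s.ci_high) for s in stats],
            "p_value": [_na(s.p_value) for s in stats],
            "p_bonferroni": [_na(s.p_bonferroni) for s in stats],
            "significant": [s.significant for s in stats],
        }
    )


def intervals_to_bed(
    intervals: Sequence[Interval], ref_name: str, name_prefix: str = "significant"
) -> str:
    """Render merged significant intervals as BED text."""
    lines = [
        f"{ref_name}\t{iv.start}\t{iv.end}\t{name_prefix}_{i + 1}"
        for i, iv in enumerate(intervals)
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def _na(value: Optional[float]) -> float:
    return np.nan if value is None else value
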