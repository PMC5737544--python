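"""Distinct-deletion grouping and RNA/DNA count-ratio quantification.

All fragments sharing the same (start, length) deletion form one "distinct
deletion" — a single allele of the edited population.  For each retained
allele the count ratio ``r = rna_count / dna_count`` estimates its relative
steady-state expression; dividing by the reference ratio (the same ratio
over no-deletion fragments) gives ``normalized_r``, the expression of the
deletion allele relative to the intact UTR.

Abundance filter: an allele is analyzable only when it is sufficiently
frequent in *both* libraries — ``count/total > 6.5e-7`` per library (the
boundary itself is eliminated).  An alternative absolute-minimum mode
(> 8 RNA and > 16 DNA reads) is available via config.  r needs a reliable
numerator and denominator, hence the per-library application; RNA-only
alleles (dna_count = 0) are excluded rather than given infinite r.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calling import FragmentCall
from .intervals import Interval
from .stats import mann_whitney_two_sided

ABUNDANCE_PER_1E7 = 6.5
ABS_MIN_RNA = 8
ABS_MIN_DNA = 16


@dataclasses.dataclass
class DistinctDeletion:
    """A unique (start, length) deletion allele with per-library counts."""

    start: int
    length: int
    dna_count: int = 0
    rna_count: int = 0
    r: Optional[float] = None
    normalized_r: Optional[float] = None
    retained: bool = False
    pilot_class: Optional[str] = None

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.start + self.length)

    @property
    def key(self) -> Tuple[int, int]:
        return (self.start, self.length)


@dataclasses.dataclass
class LibrarySummary:
    """Per-library fragment totals and the derived screen-level ratios."""

    dna_total: int
    rna_total: int
    dna_reference: int
    rna_reference: int
    total_r: Optional[float] = None

    @property
    def reference_ratio(self) -> float:
        if self.dna_reference == 0:
            raise ZeroDivisionError(
                "reference_ratio undefined: zero DNA reference fragments"
            )
        return self.rna_reference / self.dna_reference


def group_distinct(
    fragments: Iterable[FragmentCall],
) -> Tuple[List[DistinctDeletion], LibrarySummary]:
    """Group fragment calls into distinct deletions and tally the libraries.

    Discarded fragments count toward library totals (sequencing depth) but
    toward neither the reference class nor any deletion.  Deletions observed
    only in RNA are kept in the table with ``dna_count = 0`` so the caller
    can report them, but they are never retained for ratio analysis.
    """
    table: dict = {}
    totals = {"DNA": 0, "RNA": 0}
    refs = {"DNA": 0, "RNA": 0}
    for frag in fragments:
        if frag.library not in totals:
            raise ValueError(f"unknown library {frag.library!r}")
        totals[frag.library] += 1
        if frag.status == "reference":
            refs[frag.library] += 1
        elif frag.status == "deletion":
            dd = table.get(frag.call.key)
            if dd is None:
                dd = table[frag.call.key] = DistinctDeletion(
                    start=frag.call.start, length=frag.call.length
                )
            if frag.library == "DNA":
                dd.dna_count += 1
            else:
                dd.rna_count += 1
    dels = sorted(table.values(), key=lambda d: d.key)
    summary = LibrarySummary(
        dna_total=totals["DNA"],
        rna_total=totals["RNA"],
        dna_reference=refs["DNA"],
        rna_reference=refs["RNA"],
    )
    return dels, summary


def from_count_table(
    counts: pd.DataFrame, dna_total: int, rna_total: int
) -> Tuple[List[DistinctDeletion], LibrarySummary]:
    """Build distinct deletions from an allele count table.

    The table must have columns start, length, dna_count, rna_count; rows
    with start = -1 (the intact allele) feed the reference tallies.  Used by
    the fragment-count simulation mode, where each allele maps directly to
    one distinct deletion.
    """
    dels: List[DistinctDeletion] = []
    dna_ref = rna_ref = 0
    for row in counts.itertuples(index=False):
        if int(row.start) < 0:
            dna_ref += int(row.dna_count)
            rna_ref += int(row.rna_count)
        else:
            dels.append(
                DistinctDeletion(
                    start=int(row.start),
                    length=int(row.length),
                    dna_count=int(row.dna_count),
                    rna_count=int(row.rna_count),
                )
            )
    dels.sort(key=lambda d: d.key)
    return dels, LibrarySummary(
        dna_total=dna_total,
        rna_total=rna_total,
        dna_reference=dna_ref,
        rna_reference=rna_ref,
    )


def filter_abundance(
    dels: Sequence[DistinctDeletion],
    summary: LibrarySummary,
    min_per_1e7: float = ABUNDANCE_PER_1E7,
    min_length: int = 3,
    max_length: int = 29,
    mode: str = "per-library",
    abs_min_rna: int = ABS_MIN_RNA,
    abs_min_dna: int = ABS_MIN_DNA,
) -> List[DistinctDeletion]:
    """Apply the abundance and length filters; flags and returns retained alleles.

    ``per-library`` mode retains an allele only if, in both libraries,
    ``count / total > min_per_1e7 / 1e7`` (strict: the boundary is
    eliminated).  ``absolute`` mode instead requires more than
    ``abs_min_rna`` RNA and ``abs_min_dna`` DNA fragments.
    """
    if summary.dna_total <= 0 or summary.rna_total <= 0:
        raise ValueError("library totals must be positive")
    if mode not in ("per-library", "absolute"):
        raise ValueError(f"unknown abundance mode {mode!r}")
    retained = []
    for d in dels:
        ok = min_length <= d.length <= max_length
        if ok:
            if mode == "per-library":
                ok = (
                    d.dna_count * 1e7 > min_per_1e7 * summary.dna_total
                    and d.rna_count * 1e7 > min_per_1e7 * summary.rna_total
                )
            else:
                ok = d.dna_count > abs_min_dna and d.rna_count > abs_min_rna
        ok = ok and d.dna_count >= 1
        d.retained = bool(ok)
        if ok:
            retained.append(d)
    return retained


def compute_ratios(
    retained: Sequence[DistinctDeletion], summary: LibrarySummary
) -> LibrarySummary:
    """Fill in r and normalized_r for retained alleles; set screen totals.

    ``total_r`` is the pooled ratio (sum RNA)/(sum DNA) over retained
    alleles — a screen-level analog of the per-allele r, comparable to the
    reference ratio.
    """
    ref_ratio = summary.reference_ratio  # raises if undefined
    sum_rna = sum_dna = 0
    for d in retained:
        if d.dna_count < 1:
            raise ValueError(f"retained deletion {d.key} has zero DNA count")
        d.r = d.rna_count / d.dna_count
        d.normalized_r = d.r / ref_ratio
        sum_rna += d.rna_count
        sum_dna += d.dna_count
    summary.total_r = (sum_rna / sum_dna) if sum_dna else None
    return summary


def deletions_to_frame(dels: Sequence[DistinctDeletion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [d.start for d in dels],
            "length": [d.length for d in dels],
            "dna_count": [d.dna_count for d in dels],
            "rna_count": [d.rna_count for d in dels],
            "r": [d.r if d.r is not None else np.nan for d in dels],
            "normalized_r": [
                d.normalized_r if d.normalized_r is not None else np.nan for d in dels
            ],
            "retained": [d.retained for d in dels],
            "pilot_class": [d.pilot_class or "" for d in dels],
        }
    )


def frame_to_deletions(frame: pd.DataFrame) -> List[DistinctDeletion]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            DistinctDeletion(
                start=int(row.start),
                length=int(row.length),
                dna_count=int(row.dna_count),
                rna_count=int(row.rna_count),
                r=None if pd.isna(row.r) else float(row.r),
                normalized_r=None if pd.isna(row.normalized_r) else float(row.normalized_r),
                retained=bool(row.retained),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pilot-style class analysis


CLASS_INSIDE = "element"  # deletion fully inside the element
CLASS_SUPERSET = "element+"  # deletion excises the whole element plus flanks
CLASS_CONTROL = "control"  # deletion disjoint from the element


def classify_deletion(deletion: Interval, element: Interval) -> Optional[str]:
    """Assign a deletion to the element/element+/control classes.

    Deletions straddling one element boundary belong to none of the classes
    and are excluded from the pilot comparison.
    """
    if element.contains_interval(deletion):
        return CLASS_INSIDE
    if deletion.contains_interval(element):
        return CLASS_SUPERSET
    if not deletion.overlaps(element):
        return CLASS_CONTROL
    return None


@dataclasses.dataclass
class PilotResult:
    """Top-N per-class normalized ratios and the two class comparisons."""

    values: dict  # class label -> list of normalized_r (top_n by DNA count)
    p_inside_vs_control: float
    p_superset_vs_control: float


def pilot_class_analysis(
    dels: Sequence[DistinctDeletion],
    element: Interval,
    top_n: int = 9,
) -> PilotResult:
    """Pilot single-element analysis: classify deletions around one known
    element, take the ``top_n`` most abundant per class (by DNA fragment
    count — allele abundance is a DNA property), and compare normalized
    ratios of each element class against the control class with a two-sided
    Mann-Whitney test.

    Requires ``normalized_r`` (run :func:`compute_ratios` first) and at
    least 3 deletions per class.
    """
    groups: dict = {CLASS_INSIDE: [], CLASS_SUPERSET: [], CLASS_CONTROL: []}
    for d in dels:
        label = classify_deletion(d.interval, element)
        d.pilot_class = label
        if label is not None:
            groups[label].append(d)
    sizes = {k: len(v) for k, v in groups.items()}
    if any(n < 3 for n in sizes.values()):
        raise ValueError(f"fewer than 3 deletions in a class: sizes {sizes}")
    values = {}
    for label, members in groups.items():
        members.sort(key=lambda d: (-d.dna_count, d.key))
        top = members[:top_n]
        if any(d.normalized_r is None for d in top):
            raise ValueError("normalized_r missing: run compute_ratios first")
        values[label] = [d.normalized_r for d in top]
    # class groups are small (<= top_n), so the exact null is always affordable
    return PilotResult(
        values=values,
        p_inside_vs_control=mann_whitney_two_sided(
            values[CLASS_INSIDE], values[CLASS_CONTROL], exact_max=top_n
        ),
        p_superset_vs_control=mann_whitney_two_sided(
            values[CLASS_SUPERSET], values[CLASS_CONTROL], exact_max=top_n
        ),
    )
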