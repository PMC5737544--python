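"""Deletion calling from aligned paired-end amplicon reads.

Walks each alignment's CIGAR to collect deletion (D) operations with their
reference coordinates and read-end offsets, applies the screen's read-level
filters, and reconciles mate pairs into per-fragment calls:

* deletions closer than 8 nt to either read end are unreliable → the read is
  discarded;
* 1-2 nt deletions are treated as sequencing errors → the call is dropped
  but the read is kept (it counts as reference if nothing else remains);
* reads with multiple (remaining) deletions are discarded;
* deletions of 30 nt or more are discarded.

A fragment is counted once regardless of whether one or both mates show the
deletion; mates reporting inconsistent alleles are discarded as conflicts.
A fragment with no qualifying deletion is classified as reference, whether
or not its mates cover the whole UTR (unmapped/uncovered regions are assumed
deletion-free).
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
import pysam

from .intervals import Interval

# default filter thresholds
EDGE_DISTANCE = 8
MIN_DELETION_LEN = 3
MAX_DELETION_LEN = 29

#: enumerated discard reasons (countable in the run log)
DISCARD_REASONS = (
    "multi-deletion",
    "edge-proximal",
    "length-ge-30",
    "mate-conflict",
    "unmapped",
    "unsupported-cigar",
)

# CIGAR numeric codes (pysam)
_C_M, _C_I, _C_D, _C_N, _C_S, _C_H, _C_P, _C_EQ, _C_X = range(9)
_READ_OPS = {_C_M, _C_I, _C_S, _C_EQ, _C_X}
_REF_OPS = {_C_M, _C_D, _C_N, _C_EQ, _C_X}


class UnsupportedCigarError(ValueError):
    """Raised for H/P CIGAR operations (hard clips, padding)."""


@dataclasses.dataclass(frozen=True)
class DeletionCall:
    """One deletion observed on one read."""

    start: int  # 0-based reference position of the first deleted base
    length: int
    read_offset_left: int  # read bases before the junction
    read_offset_right: int  # read bases after the junction

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.start + self.length)

    @property
    def key(self) -> Tuple[int, int]:
        return (self.start, self.length)


@dataclasses.dataclass(frozen=True)
class ReadResult:
    """Outcome of the read-level filters for a single mate."""

    status: str  # 'reference' | 'deletion' | 'discarded' | 'unmapped'
    call: Optional[DeletionCall] = None
    reason: Optional[str] = None
    span: Optional[Interval] = None  # reference span of the alignment


@dataclasses.dataclass(frozen=True)
class FragmentCall:
    """Per-fragment deletion observation after mate reconciliation."""

    fragment_id: str
    library: str  # 'DNA' | 'RNA'
    status: str  # 'reference' | 'deletion' | 'discarded'
    call: Optional[DeletionCall] = None
    reason: Optional[str] = None
    covered_intervals: Tuple[Interval, ...] = ()


def extract_deletions(record: pysam.AlignedSegment) -> List[DeletionCall]:
    """Collect D (and N, treated as D) operations from a mapped record.

    M/=/X advance both reference and read, I and S advance the read only,
    D/N advance the reference only.  Offsets count all read bases including
    soft-clipped ones.  H and P operations are unsupported and raise
    :class:`UnsupportedCigarError` (the caller discards the record).
    """
    if record.is_unmapped or record.cigartuples is None:
        raise ValueError("record must be mapped with a CIGAR")
    cigar = record.cigartuples
    read_len = sum(ln for op, ln in cigar if op in _READ_OPS)
    ref_pos = record.reference_start
    read_pos = 0
    calls: List[DeletionCall] = []
    for op, ln in cigar:
        if op in (_C_H, _C_P):
            raise UnsupportedCigarError(f"unsupported CIGAR op {op} in {record.query_name}")
        if op in (_C_D, _C_N):
            calls.append(
                DeletionCall(
                    start=ref_pos,
                    length=ln,
                    read_offset_left=read_pos,
                    read_offset_right=read_len - read_pos,
                )
            )
            ref_pos += ln
        else:
            if op in _READ_OPS:
                read_pos += ln
            if op in _REF_OPS:
                ref_pos += ln
    return calls


def filter_read(
    calls: List[DeletionCall],
    edge_distance: int = EDGE_DISTANCE,
    min_length: int = MIN_DELETION_LEN,
    max_length: int = MAX_DELETION_LEN,
    span: Optional[Interval] = None,
) -> ReadResult:
    """Apply the read-level filters to the deletions seen on one read.

    Order matters: sub-``min_length`` calls are dropped first (sequencing
    errors; the read itself is kept), then multi-deletion reads, then
    edge-proximal junctions, then over-length deletions.
    """
    kept = [c for c in calls if c.length >= min_length]
    if not kept:
        return ReadResult(status="reference", span=span)
    if len(kept) > 1:
        return ReadResult(status="discarded", reason="multi-deletion", span=span)
    call = kept[0]
    if call.read_offset_left < edge_distance or call.read_offset_right < edge_distance:
        return ReadResult(status="discarded", reason="edge-proximal", span=span)
    if call.length > max_length:
        return ReadResult(status="discarded", reason="length-ge-30", span=span)
    return ReadResult(status="deletion", call=call, span=span)


def reconcile_mates(
    mate1: ReadResult, mate2: ReadResult, fragment_id: str, library: str
) -> FragmentCall:
    """Combine two mate-level results into one fragment call.

    Rules: both reference → reference; one deletion + one reference whose
    span fully covers the deletion locus (without showing it) →
    mate-conflict; both deletion with identical (start, length) → that
    deletion, counted once; both deletion but different → mate-conflict;
    any discarded mate discards the fragment with that reason; both
    unmapped → discarded(unmapped).
    """
    spans = tuple(m.span for m in (mate1, mate2) if m.span is not None)

    def done(status: str, call=None, reason=None) -> FragmentCall:
        return FragmentCall(
            fragment_id=fragment_id,
            library=library,
            status=status,
            call=call,
            reason=reason,
            covered_intervals=spans,
        )

    for mate in (mate1, mate2):
        if mate.status == "discarded":
            return done("discarded", reason=mate.reason)
    if mate1.status == "unmapped" and mate2.status == "unmapped":
        return done("discarded", reason="unmapped")

    dels = [m for m in (mate1, mate2) if m.status == "deletion"]
    others = [m for m in (mate1, mate2) if m.status != "deletion"]
    if not dels:
        return done("reference")
    if len(dels) == 2:
        if dels[0].call.key == dels[1].call.key:
            return done("deletion", call=dels[0].call)
        return done("discarded", reason="mate-conflict")
    call = dels[0].call
    other = others[0]
    if (
        other.status == "reference"
        and other.span is not None
        and other.span.contains_interval(call.interval)
    ):
        # the reference mate covers the deletion locus without showing it
        return done("discarded", reason="mate-conflict")
    return done("deletion", call=call)


def call_fragments(
    sam_path: str | Path,
    library: str,
    edge_distance: int = EDGE_DISTANCE,
    min_length: int = MIN_DELETION_LEN,
    max_length: int = MAX_DELETION_LEN,
    expected_reference: Optional[str] = None,
) -> Tuple[List[FragmentCall], Counter]:
    """Run deletion calling over a SAM file, pairing records by query name.

    Returns the per-fragment calls and a Counter of statuses/discard reasons.
    Secondary and supplementary alignments are ignored.

    Raises ``ValueError`` if ``expected_reference`` is given and the SAM
    header's reference name differs.
    """
    groups: Dict[str, List[pysam.AlignedSegment]] = defaultdict(list)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        if expected_reference is not None:
            names = list(sam.references or ())
            if names and expected_reference not in names:
                raise ValueError(
                    f"SAM reference(s) {names} do not include {expected_reference!r}"
                )
        for record in sam:
            if record.is_secondary or record.is_supplementary:
                continue
            groups[record.query_name].append(record)

    def mate_result(record: Optional[pysam.AlignedSegment]) -> ReadResult:
        if record is None or record.is_unmapped:
            return ReadResult(status="unmapped")
        span = Interval(record.reference_start, record.reference_end)
        try:
            calls = extract_deletions(record)
        except UnsupportedCigarError:
            return ReadResult(status="discarded", reason="unsupported-cigar", span=span)
        return filter_read(
            calls,
            edge_distance=edge_distance,
            min_length=min_length,
            max_length=max_length,
            span=span,
        )

    fragments: List[FragmentCall] = []
    tally: Counter = Counter()
    for qname, records in groups.items():
        r1 = records[0] if records else None
        r2 = records[1] if len(records) > 1 else None
        frag = reconcile_mates(mate_result(r1), mate_result(r2), qname, library)
        fragments.append(frag)
        tally[frag.status if frag.status != "discarded" else f"discarded:{frag.reason}"] += 1
    return fragments, tally


def fragments_to_frame(fragments: Iterable[FragmentCall]) -> pd.DataFrame:
    """Tabulate fragment calls (TSV-ready); no-deletion rows have start/length -1."""
    rows = []
    for f in fragments:
        rows.append(
            {
                "fragment_id": f.fragment_id,
                "library": f.library,
                "status": f.status,
                "start": f.call.start if f.call else -1,
                "length": f.call.length if f.call else -1,
                "reason": f.reason or "",
            }
        )
    return pd.DataFrame(rows)


def frame_to_fragments(frame: pd.DataFrame) -> List[FragmentCall]:
    """Inverse of :func:`fragments_to_frame` (offsets are not round-tripped)."""
    out = []
    for row in frame.itertuples(index=False):
        call = None
        if row.status == "deletion":
            call = DeletionCall(
                start=int(row.start),
                length=int(row.length),
                read_offset_left=EDGE_DISTANCE,
                read_offset_right=EDGE_DISTANCE,
            )
        out.append(
            FragmentCall(
                fragment_id=str(row.fragment_id),
                library=str(row.library),
                status=str(row.status),
                call=call,
                reason=str(row.reason) or None,
            )
        )
    return out
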