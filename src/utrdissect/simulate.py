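"""Synthetic CRISPR tiling-deletion screen generator.

Produces DNA/RNA amplicon read sets with known deletion alleles and known
position-dependent regulatory effects, so every downstream stage of the
pipeline can be tested against ground truth without external data.

The generator emulates the study conditions of a dual-library (genomic DNA +
cDNA) amplicon screen over a ~781-nt AT-rich 3'-UTR targeted by ~64 SpCas9
guides: a spectrum of small deletion alleles around cut sites (including
1-2 nt and >=30 nt out-of-range alleles that exercise the read filters),
150-nt paired-end reads at depths scaled down from ~80 M DNA / ~45 M cDNA
reads, substitution sequencing errors, and multiplicative effects of
deletions on RNA abundance.  A multiplier > 1 on a region models removal of
a destabilizing element (deleting it raises steady-state RNA); a multiplier
< 1 models removal of a transcription-promoting element.

Two output modes:

* :func:`simulate_reads` — full read-level output: truth-aligned SAM (with D
  CIGAR operations at each allele's deletion) plus paired FASTQ, so the
  pipeline runs without an external aligner while FASTQ preserves the option
  of using one.
* :func:`simulate_counts` — fragment-count output: multinomial allele counts
  per library, for deep-screen statistical experiments where read-level
  detail is irrelevant.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .guides import GuideSite
from .intervals import Interval
from .reference import POLYA_HEXAMER, UtrReference, annotate_polya


# ---------------------------------------------------------------------------
# effect profile / ground truth containers


@dataclasses.dataclass(frozen=True)
class EffectRegion:
    start: int
    end: int
    multiplier: float

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)


@dataclasses.dataclass
class EffectProfile:
    """Ground-truth regulatory architecture of the synthetic UTR.

    Any allele whose deletion overlaps a region has its RNA abundance
    multiplied by that region's multiplier.  ``baseline_ratio`` is the
    RNA/DNA ratio of the intact allele.
    """

    regions: List[EffectRegion] = dataclasses.field(default_factory=list)
    baseline_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be positive")
        for region in self.regions:
            if region.multiplier <= 0:
                raise ValueError("effect multipliers must be positive")
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(f"effect regions overlap: {a} / {b}")

    def multiplier_for(self, deletion: Optional[Interval]) -> float:
        """Product of multipliers of all regions the deletion overlaps (1.0 if intact)."""
        if deletion is None:
            return 1.0
        m = 1.0
        for region in self.regions:
            if region.interval.overlaps(deletion):
                m *= region.multiplier
        return m


@dataclasses.dataclass(frozen=True)
class AlleleTruth:
    """One allele of the edited population.

    ``deletion`` is None for the intact allele.  ``rna_rel`` is the
    unnormalized RNA relative abundance:
    ``dna_freq * baseline_ratio * product of overlapped multipliers``.
    """

    deletion: Optional[Interval]
    dna_freq: float
    rna_rel: float


@dataclasses.dataclass
class AlleleParams:
    """Allele-model settings for :func:`simulate_alleles`.

    ``n_draws`` allele draws are taken (duplicates collapse into one allele),
    sized so that a deep screen yields on the order of a thousand distinct
    analyzable (3-29 nt) deletions, matching the scale of a 64-guide screen.
    The deletion-length distribution is geometric-like with mode
    ``length_mode`` and support 1..``max_length``, covering both the 3-29 nt
    analysis window and the filter-rejected tails.
    """

    n_draws: int = 1500
    intact_fraction: float = 0.5
    dual_cut_probability: float = 0.05
    length_mode: int = 5
    length_decay: float = 0.75
    max_length: int = 40


@dataclasses.dataclass
class ReadParams:
    """Read-emission settings (defaults scaled down from ~80 M / ~45 M reads)."""

    dna_fragments: int = 100_000
    rna_fragments: int = 56_000
    read_length: int = 150
    error_rate: float = 0.001
    insert_mean: float = 300.0
    insert_sd: float = 40.0


@dataclasses.dataclass
class ScreenTruth:
    """Simulator ground truth: allele spectrum, frequencies and RNA effects."""

    reference: UtrReference
    alleles: List[AlleleTruth]
    profile: EffectProfile
    seed: int
    reads: ReadParams = dataclasses.field(default_factory=ReadParams)

    @property
    def dna_freqs(self) -> np.ndarray:
        return np.array([a.dna_freq for a in self.alleles])

    @property
    def rna_probs(self) -> np.ndarray:
        rel = np.array([a.rna_rel for a in self.alleles])
        return rel / rel.sum()

    def truth_frame(self) -> pd.DataFrame:
        """Allele table (TSV-ready); the intact allele has start/length -1."""
        rows = []
        for a in self.alleles:
            if a.deletion is None:
                start, length = -1, -1
            else:
                start, length = a.deletion.start, len(a.deletion)
            rows.append(
                {
                    "start": start,
                    "length": length,
                    "dna_freq": a.dna_freq,
                    "rna_rel": a.rna_rel,
                    "multiplier": self.profile.multiplier_for(a.deletion),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic reference


def make_synthetic_utr(
    seed: int = 0,
    length: int = 781,
    n_pam_sites: int = 64,
    gc_background: float = 0.15,
    name: str = "synthetic_utr",
) -> UtrReference:
    """Build an AT-rich synthetic 3'-UTR with a controlled guide landscape.

    The background sequence is drawn AT-rich, every accidental GG/CC
    dinucleotide is scrubbed, and exactly ``n_pam_sites`` PAMs are planted at
    even spacing on alternating strands, so guide enumeration finds exactly
    ``n_pam_sites`` sites.  A canonical AATAAA signal is planted 25-31 nt
    upstream of the polyA site (taken to be the reference end), and the
    reference is returned with polyA annotations set.
    """
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_background) / 2,
            gc_background / 2,
            gc_background / 2,
            (1 - gc_background) / 2,
        ]
    )
    seq = list(rng.choice(list("ACGT"), size=length, p=p))

    # scrub GG/CC so the planted PAMs are the only guide sites
    for i in range(length - 1):
        pair = seq[i] + seq[i + 1]
        if pair in ("GG", "CC"):
            seq[i + 1] = str(rng.choice(["A", "T"]))

    polya_site = length
    signal_start = length - 31
    seq[signal_start : signal_start + 6] = list(POLYA_HEXAMER)

    # plant PAMs on alternating strands, evenly spaced with small jitter
    lo, hi = 25, signal_start - 10
    spacing = (hi - lo) / n_pam_sites
    for k in range(n_pam_sites):
        pos = lo + int(round(k * spacing)) + int(rng.integers(-2, 3))
        pos = min(max(pos, lo), hi - 3)
        if k % 2 == 0:  # sense site: PAM = NGG at [pos, pos+3)
            seq[pos + 1] = "G"
            seq[pos + 2] = "G"
            for flank in (pos, pos + 3):  # avoid creating a second GG
                if seq[flank] == "G":
                    seq[flank] = str(rng.choice(["A", "T"]))
        else:  # antisense site: PAM = CCN at [pos, pos+3)
            seq[pos] = "C"
            seq[pos + 1] = "C"
            if seq[pos - 1] == "C":
                seq[pos - 1] = str(rng.choice(["A", "T"]))
            if seq[pos + 2] == "C":
                seq[pos + 2] = str(rng.choice(["A", "T"]))

    ref = UtrReference(name=name, sequence="".join(seq))
    return annotate_polya(ref, polya_site=polya_site)


# ---------------------------------------------------------------------------
# allele simulation


def _length_weights(params: AlleleParams) -> np.ndarray:
    lengths = np.arange(1, params.max_length + 1)
    w = params.length_decay ** np.abs(lengths - params.length_mode)
    return w / w.sum()


def simulate_alleles(
    ref: UtrReference,
    guides: Sequence[GuideSite],
    params: Optional[AlleleParams] = None,
    profile: Optional[EffectProfile] = None,
    seed: int = 0,
    reads: Optional[ReadParams] = None,
) -> ScreenTruth:
    """Draw a reproducible allele spectrum around the guide cut sites.

    Each draw is either a single-cut deletion (length from the geometric-like
    distribution, placed so the interval contains or abuts the cut position)
    or, with probability ``dual_cut_probability``, a dual-cut excision
    spanning two cut positions.  Duplicate (start, length) draws collapse
    into one allele.  DNA frequencies are Dirichlet-distributed over the
    deletion alleles, scaled to ``1 - intact_fraction``; the intact allele
    carries the remaining fraction.
    """
    params = params or AlleleParams()
    profile = profile or EffectProfile()
    if not guides:
        raise ValueError("at least one guide is required")
    if not 0 < params.intact_fraction <= 1:
        raise ValueError("intact_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)

    intervals: List[Interval] = []
    seen: set = set()
    if params.intact_fraction < 1.0:
        lengths = np.arange(1, params.max_length + 1)
        lweights = _length_weights(params)
        cuts = [g.cut_position for g in guides]
        for _ in range(params.n_draws):
            if len(guides) >= 2 and rng.random() < params.dual_cut_probability:
                i, j = rng.choice(len(guides), size=2, replace=False)
                c1, c2 = sorted((cuts[int(i)], cuts[int(j)]))
                if c1 == c2:
                    continue
                start, length = c1, c2 - c1
            else:
                cut = cuts[int(rng.integers(len(cuts)))]
                length = int(rng.choice(lengths, p=lweights))
                offset = int(rng.integers(0, length + 1))
                # clamp into the reference while keeping start <= cut <= end
                start = cut - offset
                start = max(start, 0, cut - length)
                start = min(start, ref.length - length, cut)
                if start < 0 or start + length > ref.length:
                    continue
            key = (start, length)
            if key not in seen:
                seen.add(key)
                intervals.append(Interval(start, start + length))

    alleles: List[AlleleTruth] = []
    if intervals:
        freqs = rng.dirichlet(np.ones(len(intervals))) * (1 - params.intact_fraction)
        for interval, freq in zip(intervals, freqs):
            mult = profile.multiplier_for(interval)
            alleles.append(
                AlleleTruth(
                    deletion=interval,
                    dna_freq=float(freq),
                    rna_rel=float(freq) * profile.baseline_ratio * mult,
                )
            )
    alleles.append(
        AlleleTruth(
            deletion=None,
            dna_freq=params.intact_fraction,
            rna_rel=params.intact_fraction * profile.baseline_ratio,
        )
    )
    return ScreenTruth(
        reference=ref,
        alleles=alleles,
        profile=profile,
        seed=seed,
        reads=reads or ReadParams(),
    )


# ---------------------------------------------------------------------------
# fragment-count simulation (deep-screen mode)


def simulate_counts(
    truth: ScreenTruth,
    seed: Optional[int] = None,
    dna_fragments: Optional[int] = None,
    rna_fragments: Optional[int] = None,
) -> Tuple[pd.DataFrame, int, int]:
    """Sample per-allele fragment counts for both libraries.

    DNA counts are multinomial over the allele DNA frequencies; RNA counts
    are multinomial over the renormalized RNA relative abundances.  Returns
    ``(count_table, dna_total, rna_total)`` where the table has one row per
    deletion allele (columns start, length, dna_count, rna_count) plus the
    intact allele flagged with start = length = -1.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    n_dna = dna_fragments if dna_fragments is not None else truth.reads.dna_fragments
    n_rna = rna_fragments if rna_fragments is not None else truth.reads.rna_fragments
    dna_counts = rng.multinomial(n_dna, truth.dna_freqs)
    rna_counts = rng.multinomial(n_rna, truth.rna_probs)
    frame = truth.truth_frame()[["start", "length"]].copy()
    frame["dna_count"] = dna_counts
    frame["rna_count"] = rna_counts
    return frame, n_dna, n_rna


# ---------------------------------------------------------------------------
# read-level simulation


@dataclasses.dataclass
class SimOutput:
    """Paths and per-fragment ground truth emitted by :func:`simulate_reads`."""

    dna_sam: Path
    rna_sam: Path
    dna_fastq1: Path
    dna_fastq2: Path
    rna_fastq1: Path
    rna_fastq2: Path
    fragments: pd.DataFrame  # fragment_id, library, start, length, frag_start, insert_len
    redraws: int


def _allele_sequence(ref: UtrReference, deletion: Optional[Interval]) -> str:
    if deletion is None:
        return ref.sequence
    return ref.sequence[: deletion.start] + ref.sequence[deletion.end :]


def _read_alignment(
    allele_start: int, read_len: int, deletion: Optional[Interval]
) -> Tuple[int, List[Tuple[int, int]]]:
    """Map a read at allele coordinate ``allele_start`` back to the reference.

    Returns (reference_start, cigartuples) where cigartuples use pysam's
    numeric codes (0 = M, 2 = D).
    """
    if deletion is None:
        return allele_start, [(0, read_len)]
    s, l = deletion.start, len(deletion)
    end = allele_start + read_len
    if end <= s:
        return allele_start, [(0, read_len)]
    if allele_start >= s:
        return allele_start + l, [(0, read_len)]
    left = s - allele_start
    return allele_start, [(0, left), (2, l), (0, read_len - left)]


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    truth: ScreenTruth,
    out_dir: str | Path,
    seed: Optional[int] = None,
    prefix: str = "screen",
) -> SimOutput:
    """Emit truth-aligned SAM and paired FASTQ for both libraries.

    Fragments are drawn from the allele DNA frequencies (DNA library) and
    renormalized RNA relative abundances (RNA library).  Each fragment yields
    a proper mate pair of ``read_length`` bases; the SAM alignment encodes
    the allele's deletion as a D CIGAR operation, so downstream deletion
    calling can run directly on the simulator output.  Substitution errors
    are applied at ``error_rate`` per base.  Fragments shorter than the read
    length are re-drawn (counted in ``redraws``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    ref = truth.reference
    rp = truth.reads

    allele_seqs = [_allele_sequence(ref, a.deletion) for a in truth.alleles]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": ref.name, "LN": ref.length}],
        }
    )

    paths = {
        ("DNA", "sam"): out_dir / f"{prefix}.dna.sam",
        ("RNA", "sam"): out_dir / f"{prefix}.rna.sam",
        ("DNA", "fq1"): out_dir / f"{prefix}.dna.r1.fastq",
        ("DNA", "fq2"): out_dir / f"{prefix}.dna.r2.fastq",
        ("RNA", "fq1"): out_dir / f"{prefix}.rna.r1.fastq",
        ("RNA", "fq2"): out_dir / f"{prefix}.rna.r2.fastq",
    }
    truth_rows = []
    redraws = 0
    qual = pysam.qualitystring_to_array("I" * rp.read_length)

    for library, n_frags, probs in (
        ("DNA", rp.dna_fragments, truth.dna_freqs),
        ("RNA", rp.rna_fragments, truth.rna_probs),
    ):
        if n_frags < 1:
            raise ValueError("library depth must be >= 1")
        counts = rng.multinomial(n_frags, probs)
        # alleles shorter than one read cannot yield a fragment: re-draw those
        # fragments from the remaining alleles and count the warning
        short = np.array([len(s) < rp.read_length for s in allele_seqs])
        if short.any():
            lost = int(counts[short].sum())
            if lost:
                redraws += lost
                counts[short] = 0
                valid_probs = np.where(short, 0.0, probs)
                valid_probs = valid_probs / valid_probs.sum()
                counts = counts + rng.multinomial(lost, valid_probs)
        sam = pysam.AlignmentFile(str(paths[(library, "sam")]), "w", header=header)
        fq1 = open(paths[(library, "fq1")], "w")
        fq2 = open(paths[(library, "fq2")], "w")
        frag_idx = 0
        try:
            for allele_idx, n in enumerate(counts):
                allele = truth.alleles[allele_idx]
                aseq = allele_seqs[allele_idx]
                alen = len(aseq)
                for _ in range(int(n)):
                    insert = int(
                        np.clip(
                            round(rng.normal(rp.insert_mean, rp.insert_sd)),
                            rp.read_length,
                            alen,
                        )
                    )
                    frag_start = int(rng.integers(0, alen - insert + 1))
                    qname = f"{library.lower()}_{frag_idx:08d}"
                    frag_idx += 1

                    r1_seq = _apply_errors(
                        aseq[frag_start : frag_start + rp.read_length], rng, rp.error_rate
                    )
                    r2_aln_seq = _apply_errors(
                        aseq[frag_start + insert - rp.read_length : frag_start + insert],
                        rng,
                        rp.error_rate,
                    )

                    pos1, cig1 = _read_alignment(frag_start, rp.read_length, allele.deletion)
                    pos2, cig2 = _read_alignment(
                        frag_start + insert - rp.read_length, rp.read_length, allele.deletion
                    )

                    a1 = pysam.AlignedSegment(header)
                    a1.query_name = qname
                    a1.query_sequence = r1_seq
                    a1.flag = 99  # paired, proper, mate reverse, first in pair
                    a1.reference_id = 0
                    a1.reference_start = pos1
                    a1.mapping_quality = 60
                    a1.cigartuples = cig1
                    a1.next_reference_id = 0
                    a1.next_reference_start = pos2
                    a1.query_qualities = qual

                    a2 = pysam.AlignedSegment(header)
                    a2.query_name = qname
                    a2.query_sequence = r2_aln_seq
                    a2.flag = 147  # paired, proper, reverse, second in pair
                    a2.reference_id = 0
                    a2.reference_start = pos2
                    a2.mapping_quality = 60
                    a2.cigartuples = cig2
                    a2.next_reference_id = 0
                    a2.next_reference_start = pos1
                    a2.query_qualities = qual

                    tlen = (pos2 + sum(l for _, l in cig2)) - pos1
                    a1.template_length = tlen
                    a2.template_length = -tlen
                    sam.write(a1)
                    sam.write(a2)

                    fq1.write(f"@{qname}/1\n{r1_seq}\n+\n{'I' * rp.read_length}\n")
                    r2_sequenced = str(Seq(r2_aln_seq).reverse_complement())
                    fq2.write(f"@{qname}/2\n{r2_sequenced}\n+\n{'I' * rp.read_length}\n")

                    if allele.deletion is None:
                        start, length = -1, -1
                    else:
                        start, length = allele.deletion.start, len(allele.deletion)
                    truth_rows.append(
                        {
                            "fragment_id": qname,
                            "library": library,
                            "start": start,
                            "length": length,
                            "frag_start": frag_start,
                            "insert_len": insert,
                        }
                    )
        finally:
            sam.close()
            fq1.close()
            fq2.close()

    return SimOutput(
        dna_sam=paths[("DNA", "sam")],
        rna_sam=paths[("RNA", "sam")],
        dna_fastq1=paths[("DNA", "fq1")],
        dna_fastq2=paths[("DNA", "fq2")],
        rna_fastq1=paths[("RNA", "fq1")],
        rna_fastq2=paths[("RNA", "fq2")],
        fragments=pd.DataFrame(truth_rows),
        redraws=redraws,
    )
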