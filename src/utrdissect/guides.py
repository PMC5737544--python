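"""SpCas9 guide enumeration and dual-guide excision design for a 3'-UTR.

Enumerates every protospacer+NGG site on both strands of the reference and
builds the paired-guide design used to excise the bulk of a 3'-UTR: the
proximal cut just downstream of the stop codon (antisense guide, so the PAM
sits inside the UTR rather than in coding sequence) and the distal cut
upstream of the polyA signal (sense guide, PAM 5' of the signal).

Cut geometry: SpCas9 makes a blunt cut between protospacer positions 17 and
18, i.e. 3 bp 5' of the PAM on the protospacer strand. ``cut_position`` is
the between-base reference coordinate of that cut (the 0-based position of
the first base 3' of the cut on the reference strand).
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import pandas as pd
from Bio.Seq import Seq

from .intervals import Interval
from .reference import UtrReference

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: distance from the PAM-proximal protospacer end to the blunt cut
CUT_OFFSET = 3


@dataclasses.dataclass(frozen=True)
class GuideSite:
    """One SpCas9 recognition site (protospacer + NGG PAM).

    ``protospacer`` is given 5'->3' on the guide's own strand.  All intervals
    are half-open on the reference strand regardless of guide strand.
    """

    protospacer: str
    strand: str  # '+' or '-'
    protospacer_start: int
    pam_start: int
    cut_position: int

    @property
    def protospacer_interval(self) -> Interval:
        return Interval(self.protospacer_start, self.protospacer_start + PROTOSPACER_LEN)

    @property
    def pam_interval(self) -> Interval:
        return Interval(self.pam_start, self.pam_start + PAM_LEN)


@dataclasses.dataclass(frozen=True)
class DualGuidePair:
    """A proximal (antisense) / distal (sense) guide pair and the excision it programs."""

    proximal: GuideSite
    distal: GuideSite

    @property
    def expected_deletion(self) -> Interval:
        return Interval(self.proximal.cut_position, self.distal.cut_position)


class GuideDesignError(ValueError):
    """No guide satisfies the placement constraints; message names the side."""


def enumerate_guides(ref: UtrReference) -> List[GuideSite]:
    """Enumerate all protospacer+NGG sites on both strands.

    Every position where a 20-nt protospacer immediately followed (on its own
    strand) by NGG fits fully inside the reference yields exactly one site.
    No further filters (uniqueness, GC content, synthesis constraints) are
    applied.  Output is sorted by ``cut_position`` then strand ('+' first).
    """
    seq = ref.sequence
    n = len(seq)
    sites: List[GuideSite] = []
    # sense strand: protospacer [i, i+20), PAM [i+20, i+23) = NGG
    for i in range(0, n - (PROTOSPACER_LEN + PAM_LEN) + 1):
        if seq[i + 21] == "G" and seq[i + 22] == "G":
            sites.append(
                GuideSite(
                    protospacer=seq[i : i + PROTOSPACER_LEN],
                    strand="+",
                    protospacer_start=i,
                    pam_start=i + PROTOSPACER_LEN,
                    cut_position=i + PROTOSPACER_LEN - CUT_OFFSET,
                )
            )
    # antisense strand: on the reference the PAM reads CCN at [j, j+3),
    # protospacer [j+3, j+23); the guide sequence is the reverse complement.
    for j in range(0, n - (PROTOSPACER_LEN + PAM_LEN) + 1):
        if seq[j] == "C" and seq[j + 1] == "C":
            proto_ref = seq[j + PAM_LEN : j + PAM_LEN + PROTOSPACER_LEN]
            sites.append(
                GuideSite(
                    protospacer=str(Seq(proto_ref).reverse_complement()),
                    strand="-",
                    protospacer_start=j + PAM_LEN,
                    pam_start=j,
                    cut_position=j + PAM_LEN + CUT_OFFSET,
                )
            )
    sites.sort(key=lambda s: (s.cut_position, s.strand))
    return sites


def design_dual_pair(
    ref: UtrReference,
    guides: Optional[List[GuideSite]] = None,
) -> DualGuidePair:
    """Pick the dual-guide pair that excises the largest UTR span.

    Placement rules:

    * proximal guide: antisense strand, PAM within the UTR (at or after
      ``stop_codon_end`` so no coding/stop sequence is deleted); among valid
      candidates the smallest ``cut_position`` is chosen.
    * distal guide: sense strand, PAM entirely 5' of the polyA signal (so the
      signal survives the excision); the largest ``cut_position`` is chosen.

    The maximal-span choice follows from the design goal of excising the
    majority of the UTR.
    """
    if ref.polya_signal is None:
        raise GuideDesignError("reference has no polya_signal annotation")
    if guides is None:
        guides = enumerate_guides(ref)
    signal = ref.polya_signal

    proximal_candidates = [
        g
        for g in guides
        if g.strand == "-"
        and g.pam_start >= ref.stop_codon_end
        and g.cut_position >= ref.stop_codon_end
        and g.cut_position < signal.start
    ]
    if not proximal_candidates:
        raise GuideDesignError(
            "proximal: no antisense guide with PAM inside the proximal 3'-UTR"
        )
    proximal = min(proximal_candidates, key=lambda g: g.cut_position)

    distal_candidates = [
        g
        for g in guides
        if g.strand == "+"
        and g.pam_start + PAM_LEN <= signal.start
        and g.cut_position > proximal.cut_position
    ]
    if not distal_candidates:
        raise GuideDesignError(
            "distal: no sense guide with PAM entirely upstream of the polyA signal"
        )
    distal = max(distal_candidates, key=lambda g: g.cut_position)

    pair = DualGuidePair(proximal=proximal, distal=distal)
    deletion = pair.expected_deletion
    assert not deletion.overlaps(signal)
    assert deletion.start >= ref.stop_codon_end
    return pair


def guides_to_frame(guides: List[GuideSite]) -> pd.DataFrame:
    """Tabulate guide sites (TSV-ready)."""
    return pd.DataFrame(
        {
            "protospacer": [g.protospacer for g in guides],
            "strand": [g.strand for g in guides],
            "protospacer_start": [g.protospacer_start for g in guides],
            "pam_start": [g.pam_start for g in guides],
            "cut_position": [g.cut_position for g in guides],
        }
    )


def pair_to_frame(pair: DualGuidePair) -> pd.DataFrame:
    rows = []
    for role, g in (("proximal", pair.proximal), ("distal", pair.distal)):
        rows.append(
            {
                "role": role,
                "protospacer": g.protospacer,
                "strand": g.strand,
                "protospacer_start": g.protospacer_start,
                "pam_start": g.pam_start,
                "cut_position": g.cut_position,
                "deletion_start": pair.expected_deletion.start,
                "deletion_end": pair.expected_deletion.end,
            }
        )
    return pd.DataFrame(rows)
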