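"""3'-UTR reference handling.

A screen runs against a single short reference — the 3'-UTR amplicon — so the
reference model is deliberately small: one named sequence over {A,C,G,T}, a
0-based coordinate frame with half-open intervals, and optional annotations
for the cleavage/polyadenylation site and the polyA signal hexamer.

The polyA signal matters for guide design: the distal cut must stay upstream
of it so that excising UTR sequence does not abolish polyadenylation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Interval

VALID_BASES = frozenset("ACGT")

#: canonical polyadenylation signal hexamer, DNA alphabet
POLYA_HEXAMER = "AATAAA"

#: the hexamer must lie wholly 10-35 nt upstream of the cleavage site
POLYA_WINDOW_NEAR = 10
POLYA_WINDOW_FAR = 35


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T); reject anything else.

    Raises
    ------
    ValueError
        naming the 0-based position of the first non-ACGTU character.
    """
    out = seq.upper().replace("U", "T")
    for i, base in enumerate(out):
        if base not in VALID_BASES:
            raise ValueError(
                f"invalid base {base!r} at position {i}: sequence must "
                "contain only A/C/G/T (or U)"
            )
    return out


@dataclasses.dataclass
class UtrReference:
    """A 3'-UTR reference sequence with its coordinate conventions.

    All positions are 0-based; intervals are half-open ``[start, end)``.

    Parameters
    ----------
    name : str
        Sequence identifier (used as the SAM reference name).
    sequence : str
        DNA sequence; normalized to uppercase A/C/G/T on construction.
    polya_site : int, optional
        Cleavage/polyA site: one past the last transcribed base.
    polya_signal : Interval, optional
        Half-open interval of the signal hexamer; length must be 6.
    stop_codon_end : int
        Position where the 3'-UTR begins (0 for a UTR-only reference).
    """

    name: str
    sequence: str
    polya_site: Optional[int] = None
    polya_signal: Optional[Interval] = None
    stop_codon_end: int = 0

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.polya_signal is not None:
            sig = Interval(*self.polya_signal)
            if not (0 <= sig.start < sig.end <= self.length):
                raise ValueError(f"polya_signal {sig} outside [0, {self.length})")
            if len(sig) != 6:
                raise ValueError(f"polya_signal must span 6 nt, got {len(sig)}")
            self.polya_signal = sig
        if self.polya_site is not None and not 0 <= self.polya_site <= self.length:
            raise ValueError(f"polya_site {self.polya_site} outside [0, {self.length}]")
        if not 0 <= self.stop_codon_end <= self.length:
            raise ValueError("stop_codon_end outside reference")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return self.length

    def reverse_complement(self) -> str:
        return str(Seq(self.sequence).reverse_complement())

    def to_fasta(self, path: str | Path) -> Path:
        """Write the reference as a single-record FASTA file."""
        path = Path(path)
        record = SeqRecord(Seq(self.sequence), id=self.name, description="")
        with open(path, "w") as handle:
            SeqIO.write([record], handle, "fasta")
        return path


def load_reference(
    path: str | Path,
    name: Optional[str] = None,
    polya_site: Optional[int] = None,
    stop_codon_end: int = 0,
) -> UtrReference:
    """Load a 3'-UTR reference from FASTA.

    The file must contain exactly one record, unless ``name`` selects one of
    several. The sequence is normalized (uppercased, U->T); any other
    character is a hard error naming the offending position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if name is None:
        if len(records) > 1:
            ids = ", ".join(r.id for r in records[:5])
            raise ValueError(
                f"{path} contains {len(records)} records ({ids} ...); "
                "select one with name="
            )
        record = records[0]
    else:
        matches = [r for r in records if r.id == name]
        if not matches:
            raise ValueError(f"record {name!r} not found in {path}")
        record = matches[0]
    return UtrReference(
        name=record.id,
        sequence=str(record.seq),
        polya_site=polya_site,
        stop_codon_end=stop_codon_end,
    )


def find_polya_signal(
    ref: UtrReference, polya_site: int, strict: bool = False
) -> Optional[Interval]:
    """Locate the canonical AATAAA signal upstream of the polyA site.

    The hexamer must lie fully within 10-35 nt upstream of ``polya_site``:
    its start ``s`` satisfies ``polya_site - 35 <= s`` and
    ``s + 6 <= polya_site - 10``.  When several hexamers qualify, the 5'-most
    (smallest start) is returned — the most distal from the cleavage site,
    which maximizes the sequence available downstream of the distal cut.

    Returns ``None`` when no canonical hexamer is present; the caller must
    then supply the signal position manually (e.g. from a config file).

    Parameters
    ----------
    strict : bool
        When True, a polyA site closer than 35 nt to the reference start is
        an error; otherwise the search window is truncated at 0.
    """
    if not 0 <= polya_site <= ref.length:
        raise ValueError(f"polya_site {polya_site} outside reference")
    lo = polya_site - POLYA_WINDOW_FAR
    if lo < 0:
        if strict:
            raise ValueError(
                f"polya_site {polya_site} is closer than {POLYA_WINDOW_FAR} nt "
                "to the reference start"
            )
        lo = 0
    hi = polya_site - POLYA_WINDOW_NEAR - len(POLYA_HEXAMER)  # last valid start
    for s in range(lo, hi + 1):
        if ref.sequence[s : s + 6] == POLYA_HEXAMER:
            return Interval(s, s + 6)
    return None


def annotate_polya(
    ref: UtrReference,
    polya_site: int,
    signal_start: Optional[int] = None,
    strict: bool = False,
) -> UtrReference:
    """Return a copy of ``ref`` with polyA site and signal annotated.

    ``signal_start`` overrides the canonical-hexamer search (the escape hatch
    for UTRs lacking AATAAA in the 10-35 nt window, where the signal position
    must come from an external prediction supplied by the user).
    """
    if signal_start is not None:
        signal: Optional[Interval] = Interval(signal_start, signal_start + 6)
    else:
        signal = find_polya_signal(ref, polya_site, strict=strict)
    return dataclasses.replace(ref, polya_site=polya_site, polya_signal=signal)
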