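"""Run configuration: every numeric constant of the pipeline in one place.

The config is a TOML file; all thresholds default to the screen's standard
values and are echoed into the run log so that any output can be reproduced
from (inputs, config, seed) alone.  The ``aligner`` block is documentation
only: it records the recommended external-aligner settings (end-to-end
alignment, at most 20 mismatches, at least 40 matched bases, no multiple
alignments) for users who align FASTQ themselves — this pipeline consumes
SAM and never runs an aligner.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Optional


@dataclasses.dataclass
class SimConfig:
    """Simulator block (synthetic screens)."""

    seed: int = 0
    utr_length: int = 781
    n_pam_sites: int = 64
    dna_fragments: int = 100_000
    rna_fragments: int = 56_000
    read_length: int = 150
    error_rate: float = 0.001
    intact_fraction: float = 0.5
    n_draws: int = 1500
    dual_cut_probability: float = 0.05
    # effect regions as [[start, end, multiplier], ...]
    effect_regions: list = dataclasses.field(default_factory=list)
    baseline_ratio: float = 1.0


@dataclasses.dataclass
class RunConfig:
    """Pipeline thresholds and inputs."""

    reference: Optional[str] = None
    polya_site: Optional[int] = None
    polya_signal_start: Optional[int] = None  # manual override (no prediction)
    stop_codon_end: int = 0

    edge_distance: int = 8
    min_len: int = 3
    max_len: int = 29
    abundance_per_1e7: float = 6.5
    abundance_mode: str = "per-library"  # or "absolute" (>16 DNA and >8 RNA)
    abs_min_rna: int = 8
    abs_min_dna: int = 16

    bootstrap_reps: int = 1000
    seed: int = 0
    alpha: float = 0.05
    min_deletions_per_position: int = 4

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    aligner: dict = dataclasses.field(
        default_factory=lambda: {
            "mode": "end-to-end",
            "max_mismatches": 20,
            "min_matched_bases": 40,
            "multiple_alignments": False,
        }
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        for name in (
            "edge_distance",
            "min_len",
            "max_len",
            "abundance_per_1e7",
            "bootstrap_reps",
            "min_deletions_per_position",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.abundance_mode not in ("per-library", "absolute"):
            raise ValueError(f"unknown abundance_mode {self.abundance_mode!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        sim = SimConfig(**data.pop("sim", {}))
        aligner = data.pop("aligner", None)
        cfg = cls(sim=sim, **data)
        if aligner:
            cfg.aligner.update(aligner)
        return cfg

    def log_lines(self) -> list[str]:
        """Echo every constant (one line each) for the run log."""
        out = []
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            out.append(f"config {field.name} = {value!r}")
        return out
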