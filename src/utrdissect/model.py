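"""Model/Results interface for the deletion screen.

`UtrDeletionScreen` wraps a screen's observed data (distinct deletions plus
library totals) the way a statsmodels model wraps an endog/exog pair;
`fit()` runs the filtering, ratio computation and per-position inference and
returns a `ScreenResults` carrying the estimates, their bootstrap
uncertainties, the test diagnostics and a `summary()` table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import calling, positions, quantify
from .intervals import Interval
from .quantify import DistinctDeletion, LibrarySummary
from .reference import UtrReference


class UtrDeletionScreen:
    """A CRISPR tiling-deletion screen over one 3'-UTR.

    Parameters
    ----------
    deletions : sequence of DistinctDeletion
        The grouped (start, length) alleles with per-library counts
        (pre-filter).
    summary : LibrarySummary
        Library totals and reference-fragment counts.
    reference : UtrReference or int
        The reference itself, or just its length.

    Filter thresholds default to the screen's standard values: a deletion is
    analyzable when 3-29 nt long and above 6.5 fragments per 1e7 in both
    libraries, and a position is analyzed when involved in >= 4 retained
    distinct deletions.
    """

    def __init__(
        self,
        deletions: Sequence[DistinctDeletion],
        summary: LibrarySummary,
        reference: UtrReference | int,
        min_length: int = 3,
        max_length: int = 29,
        abundance_per_1e7: float = quantify.ABUNDANCE_PER_1E7,
        abundance_mode: str = "per-library",
        min_deletions_per_position: int = positions.MIN_DELETIONS_PER_POSITION,
    ):
        self.deletions = list(deletions)
        self.summary = summary
        if isinstance(reference, UtrReference):
            self.reference: Optional[UtrReference] = reference
            self.ref_length = reference.length
            self.ref_name = reference.name
        else:
            self.reference = None
            self.ref_length = int(reference)
            self.ref_name = "reference"
        self.min_length = min_length
        self.max_length = max_length
        self.abundance_per_1e7 = abundance_per_1e7
        self.abundance_mode = abundance_mode
        self.min_deletions_per_position = min_deletions_per_position

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_sam(
        cls,
        dna_sam: str | Path,
        rna_sam: str | Path,
        reference: UtrReference,
        edge_distance: int = calling.EDGE_DISTANCE,
        **kwargs,
    ) -> "UtrDeletionScreen":
        """Run deletion calling on the two libraries' SAM files and group."""
        min_length = kwargs.get("min_length", 3)
        max_length = kwargs.get("max_length", 29)
        fragments: List[calling.FragmentCall] = []
        tallies = {}
        for path, library in ((dna_sam, "DNA"), (rna_sam, "RNA")):
            frags, tally = calling.call_fragments(
                path,
                library,
                edge_distance=edge_distance,
                min_length=min_length,
                max_length=max_length,
                expected_reference=reference.name,
            )
            fragments.extend(frags)
            tallies[library] = tally
        dels, summary = quantify.group_distinct(fragments)
        model = cls(dels, summary, reference, **kwargs)
        model.call_tallies = tallies
        return model

    @classmethod
    def from_count_table(
        cls,
        counts: pd.DataFrame,
        dna_total: int,
        rna_total: int,
        reference: UtrReference | int,
        **kwargs,
    ) -> "UtrDeletionScreen":
        """Build from an allele count table (fragment-count simulation mode)."""
        dels, summary = quantify.from_count_table(counts, dna_total, rna_total)
        return cls(dels, summary, reference, **kwargs)

    # -- estimation ---------------------------------------------------------

    def fit(
        self,
        alpha: float = 0.05,
        n_boot: int = 1000,
        seed: int = 0,
        compute_ci: bool = True,
    ) -> "ScreenResults":
        """Filter, compute ratios, and build the per-position activity map."""
        retained = quantify.filter_abundance(
            self.deletions,
            self.summary,
            min_per_1e7=self.abundance_per_1e7,
            min_length=self.min_length,
            max_length=self.max_length,
            mode=self.abundance_mode,
        )
        quantify.compute_ratios(retained, self.summary)
        stats, intervals = positions.build_map(
            retained,
            ref_length=self.ref_length,
            reference_ratio=self.summary.reference_ratio,
            alpha=alpha,
            n_boot=n_boot,
            seed=seed,
            min_deletions=self.min_deletions_per_position,
            compute_ci=compute_ci,
        )
        return ScreenResults(
            model=self,
            retained=retained,
            position_stats=stats,
            significant_intervals=intervals,
            alpha=alpha,
            n_boot=n_boot,
            seed=seed,
        )


@dataclasses.dataclass
class ScreenResults:
    """Fitted activity map with estimates, uncertainties and diagnostics."""

    model: UtrDeletionScreen
    retained: List[DistinctDeletion]
    position_stats: List[positions.PositionStat]
    significant_intervals: List[Interval]
    alpha: float
    n_boot: int
    seed: int

    @property
    def summary_stats(self) -> LibrarySummary:
        return self.model.summary

    @property
    def reference_ratio(self) -> float:
        return self.model.summary.reference_ratio

    @property
    def total_r(self) -> Optional[float]:
        return self.model.summary.total_r

    @property
    def n_distinct(self) -> int:
        return len(self.retained)

    @property
    def n_analyzed_positions(self) -> int:
        return sum(1 for s in self.position_stats if s.analyzed)

    @property
    def position_frame(self) -> pd.DataFrame:
        return positions.map_to_frame(self.position_stats)

    def median_normalized_r(self, interval: Interval) -> float:
        """Median over an interval of the per-position median normalized r."""
        vals = [
            s.median_normalized_r
            for s in self.position_stats
            if interval.contains(s.position) and s.median_normalized_r is not None
        ]
        if not vals:
            raise ValueError(f"no analyzed positions in {interval}")
        return float(np.median(vals))

    def summary(self) -> str:
        """Plain-text summary table of the fitted screen."""
        s = self.model.summary
        lines = [
            "       3'-UTR Deletion Screen Activity Map",
            "=" * 52,
            f"{'Reference':<36}{self.model.ref_name}",
            f"{'Reference length (nt)':<36}{self.model.ref_length}",
            f"{'DNA fragments (total)':<36}{s.dna_total}",
            f"{'RNA fragments (total)':<36}{s.rna_total}",
            f"{'Reference ratio (RNA/DNA)':<36}{s.reference_ratio:.4f}",
            f"{'Total r (retained deletions)':<36}"
            + (f"{s.total_r:.4f}" if s.total_r is not None else "NA"),
            f"{'Distinct deletions retained':<36}{self.n_distinct}",
            f"{'Positions analyzed (n >= 4)':<36}{self.n_analyzed_positions}",
            f"{'Bootstrap replicates':<36}{self.n_boot}",
            f"{'Family-wise alpha (Bonferroni)':<36}{self.alpha}",
            f"{'Significant positions':<36}"
            + str(sum(1 for st in self.position_stats if st.significant)),
            f"{'Significant intervals':<36}"
            + (
                ", ".join(str(iv) for iv in self.significant_intervals)
                if self.significant_intervals
                else "none"
            ),
            "=" * 52,
        ]
        return "\n".join(lines)

    # -- output -------------------------------------------------------------

    def to_position_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.position_frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path

    def to_bed(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            positions.intervals_to_bed(self.significant_intervals, self.model.ref_name)
        )
        return path

    def to_deletion_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        quantify.deletions_to_frame(self.model.deletions).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )
        return path

    def plot_track(self, ax=None, normalized: bool = True):
        """Plot the activity track: per-position median (normalized) r with
        its CI band and significant positions highlighted."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        frame = self.position_frame
        analyzed = frame[frame["analyzed"]]
        scale = self.reference_ratio if normalized else 1.0
        y = analyzed["median_r"] / scale
        ax.plot(analyzed["position"], y, color="0.2", lw=1, label="median")
        if analyzed["ci_low"].notna().any():
            ax.fill_between(
                analyzed["position"],
                analyzed["ci_low"] / scale,
                analyzed["ci_high"] / scale,
                color="0.7",
                alpha=0.5,
                label="95% CI",
            )
        sig = analyzed[analyzed["significant"]]
        ax.scatter(
            sig["position"],
            sig["median_r"] / scale,
            color="red",
            s=8,
            zorder=3,
            label="significant",
        )
        ax.axhline(1.0 if normalized else self.reference_ratio, ls="--", color="0.5", lw=0.8)
        ax.set_xlabel("position (nt)")
        ax.set_ylabel("median normalized r" if normalized else "median r")
        ax.legend(fontsize=8, frameon=False)
        return ax
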