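"""Quantification formulas for the replicate-level wet-lab assays.

Four ratio statistics, each on qPCR-style normalized expression values:

* reporter effect — (normalized reporter mRNA with the test UTR) /
  (mean normalized reporter mRNA of the empty reporter);
* decay fraction — remaining mRNA after the chase,
  (target/reference at t4) / (target/reference at t0); < 1 means less
  stable than the reference gene, > 1 more stable;
* new-transcription ratio — (normalized target after a 20-min metabolic
  pulse) / (mean wild-type normalized pulse signal); presented as a
  percent reduction, 100 * (1 - ratio);
* enhancer activity — (normalized reporter mRNA) / (normalized reporter
  DNA), with fold change versus the minimal-promoter-only control.

All four are scale-invariant in the raw levels.  Summaries are mean +/- s.d.
(sample s.d., ddof=1).  Replicate-level significance testing is a thin
pass-through to standard routines (two-sided t-test; Dunnett versus a shared
control) and is not re-derived here.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass
class AssayResult:
    """Per-replicate ratios with their mean +/- s.d. summary."""

    values: np.ndarray
    mean: float
    sd: float

    @property
    def percent_reduction(self) -> float:
        """Presentation convention: a ratio of 0.18 is an 82% reduction."""
        return 100.0 * (1.0 - self.mean)


def _ratios(target: Sequence[float], reference: Sequence[float]) -> np.ndarray:
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.shape != reference.shape:
        raise ValueError("target and reference must have matching replicates")
    if np.any(reference <= 0):
        raise ValueError("reference levels must be positive")
    if np.any(target < 0):
        raise ValueError("target levels must be non-negative")
    return target / reference


def _result(values: np.ndarray) -> AssayResult:
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return AssayResult(values=values, mean=float(values.mean()), sd=sd)


def reporter_effect(
    test_target: Sequence[float],
    test_reference: Sequence[float],
    empty_target: Sequence[float],
    empty_reference: Sequence[float],
) -> AssayResult:
    """Steady-state reporter effect of a 3'-UTR.

    Each test replicate's normalized reporter level is divided by the mean
    normalized level of the empty-reporter replicates.
    """
    test = _ratios(test_target, test_reference)
    empty = _ratios(empty_target, empty_reference)
    denom = empty.mean()
    if denom <= 0:
        raise ValueError("empty-reporter mean normalized level must be positive")
    return _result(test / denom)


def decay_fraction(
    t4_target: Sequence[float],
    t4_reference: Sequence[float],
    t0_target: Sequence[float],
    t0_reference: Sequence[float],
) -> AssayResult:
    """Fraction of mRNA remaining after the 4-h chase, replicate-paired."""
    t4 = _ratios(t4_target, t4_reference)
    t0 = _ratios(t0_target, t0_reference)
    if np.any(t0 <= 0):
        raise ValueError("t0 normalized level must be positive")
    return _result(t4 / t0)


def new_transcription_ratio(
    targeted_target: Sequence[float],
    targeted_reference: Sequence[float],
    wildtype_target: Sequence[float],
    wildtype_reference: Sequence[float],
) -> AssayResult:
    """Newly synthesized transcript level relative to wild type.

    Per-replicate normalized pulse signal of the targeted cells over the
    mean wild-type normalized pulse signal.
    """
    targeted = _ratios(targeted_target, targeted_reference)
    wildtype = _ratios(wildtype_target, wildtype_reference)
    denom = wildtype.mean()
    if denom <= 0:
        raise ValueError("wild-type mean normalized level must be positive")
    return _result(targeted / denom)


@dataclasses.dataclass
class EnhancerResult(AssayResult):
    fold_change: Optional[float] = None  # vs minimal-promoter-only control


def enhancer_activity(
    mrna_target: Sequence[float],
    mrna_reference: Sequence[float],
    dna_target: Sequence[float],
    dna_reference: Sequence[float],
    control_activity: Optional[Sequence[float]] = None,
) -> EnhancerResult:
    """Enhancer activity: normalized reporter mRNA over normalized reporter DNA.

    When the minimal-promoter-only control's activities are supplied, the
    fold change of the mean activity over the control mean is reported.
    """
    mrna = _ratios(mrna_target, mrna_reference)
    dna = _ratios(dna_target, dna_reference)
    if np.any(dna <= 0):
        raise ValueError("normalized DNA level must be positive")
    base = _result(mrna / dna)
    fold = None
    if control_activity is not None:
        control_mean = float(np.mean(np.asarray(control_activity, dtype=float)))
        if control_mean <= 0:
            raise ValueError("control activity mean must be positive")
        fold = base.mean / control_mean
    return EnhancerResult(values=base.values, mean=base.mean, sd=base.sd, fold_change=fold)


# ---------------------------------------------------------------------------
# thin wrappers around standard replicate-level tests


def ttest_two_sided(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Student's t-test p-value (pass-through)."""
    return float(sps.ttest_ind(np.asarray(a, float), np.asarray(b, float)).pvalue)


def dunnett_vs_control(
    control: Sequence[float], *groups: Sequence[float]
) -> np.ndarray:
    """Dunnett's many-to-one comparison p-values (pass-through)."""
    res = sps.dunnett(*[np.asarray(g, float) for g in groups], control=np.asarray(control, float))
    return np.asarray(res.pvalue)
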