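"""Distinct-deletion grouping, abundance filtering, ratios and pilot classes."""

from math import comb

import numpy as np
import pytest

import utrdissect as u
from utrdissect.calling import DeletionCall, FragmentCall
from utrdissect.quantify import (
    CLASS_CONTROL,
    CLASS_INSIDE,
    CLASS_SUPERSET,
    DistinctDeletion,
    LibrarySummary,
    classify_deletion,
    filter_abundance,
)


def frag(library, start=None, length=None, status=None, fid="f"):
    if status is None:
        status = "deletion" if start is not None else "reference"
    call = (
        DeletionCall(start, length, 20, 20) if status == "deletion" else None
    )
    return FragmentCall(fragment_id=fid, library=library, status=status, call=call)


class TestGroupDistinct:
    def test_counts_per_key(self):
        frags = [frag("DNA", 40, 5) for _ in range(3)] + [
            frag("RNA", 40, 5) for _ in range(2)
        ]
        dels, summary = u.group_distinct(frags)
        assert len(dels) == 1
        assert (dels[0].dna_count, dels[0].rna_count) == (3, 2)
        assert summary.dna_total == 3 and summary.rna_total == 2

    def test_distinct_keys_stay_distinct(self):
        dels, _ = u.group_distinct([frag("DNA", 40, 5), frag("DNA", 41, 5)])
        assert [d.key for d in dels] == [(40, 5), (41, 5)]

    def test_rna_only_deletion_never_retained(self):
        frags = [frag("RNA", 60, 4) for _ in range(5)]
        frags += [frag("DNA", status="reference") for _ in range(5)]
        dels, summary = u.group_distinct(frags)
        assert dels[0].dna_count == 0
        retained = filter_abundance(dels, summary)
        assert retained == []
        assert dels[0].r is None

    def test_discarded_count_in_totals_only(self):
        frags = [frag("DNA", status="reference"), frag("DNA", status="discarded")]
        _, summary = u.group_distinct(frags)
        assert summary.dna_total == 2
        assert summary.dna_reference == 1


class TestAbundanceFilter:
    def summary(self, dna_total=10_000_000, rna_total=10_000_000):
        return LibrarySummary(
            dna_total=dna_total, rna_total=rna_total, dna_reference=100, rna_reference=100
        )

    def dd(self, dna, rna, length=5):
        return DistinctDeletion(start=10, length=length, dna_count=dna, rna_count=rna)

    def test_sixteen_of_1e7_passes(self):
        # 16/1e7 > 6.5e-7 on the DNA side
        retained = filter_abundance([self.dd(16, 100)], self.summary())
        assert len(retained) == 1

    def test_six_of_1e7_eliminated(self):
        retained = filter_abundance([self.dd(100, 6)], self.summary())
        assert retained == []

    def test_exact_boundary_eliminated(self):
        # 65 of 1e8 is exactly 6.5 per 1e7: the boundary is eliminated
        retained = filter_abundance(
            [self.dd(65, 1000)], self.summary(dna_total=100_000_000)
        )
        assert retained == []
        retained = filter_abundance(
            [self.dd(66, 1000)], self.summary(dna_total=100_000_000)
        )
        assert len(retained) == 1

    @pytest.mark.parametrize("length,kept", [(2, False), (3, True), (29, True), (30, False)])
    def test_length_window(self, length, kept):
        retained = filter_abundance([self.dd(100, 100, length=length)], self.summary())
        assert bool(retained) == kept

    def test_absolute_mode(self):
        s = self.summary(dna_total=1000, rna_total=1000)
        assert filter_abundance([self.dd(16, 9)], s, mode="absolute") == []
        assert filter_abundance([self.dd(17, 8)], s, mode="absolute") == []
        assert len(filter_abundance([self.dd(17, 9)], s, mode="absolute")) == 1

    def test_monotone_in_counts(self):
        """Increasing counts never flips retained -> eliminated."""
        rng = np.random.default_rng(0)
        s = self.summary(dna_total=100_000, rna_total=50_000)
        for _ in range(200):
            dna, rna = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            base = bool(filter_abundance([self.dd(dna, rna)], s))
            bumped = bool(filter_abundance([self.dd(dna + 1, rna + 1)], s))
            assert bumped >= base


class TestComputeRatios:
    def test_ratio_values(self):
        dels = [DistinctDeletion(10, 5, dna_count=20, rna_count=10, retained=True)]
        summary = LibrarySummary(100, 100, dna_reference=40, rna_reference=20)
        u.compute_ratios(dels, summary)
        assert dels[0].r == 0.5
        assert dels[0].normalized_r == 1.0  # reference ratio is also 0.5
        assert summary.total_r == 0.5

    def test_zero_rna_gives_zero_r(self):
        dels = [DistinctDeletion(10, 5, dna_count=20, rna_count=0, retained=True)]
        summary = LibrarySummary(100, 100, dna_reference=40, rna_reference=20)
        u.compute_ratios(dels, summary)
        assert dels[0].r == 0.0

    def test_undefined_reference_ratio_is_hard_error(self):
        summary = LibrarySummary(100, 100, dna_reference=0, rna_reference=20)
        with pytest.raises(ZeroDivisionError, match="reference_ratio undefined"):
            u.compute_ratios([], summary)

    def test_totals_stable_under_equal_subsampling(self, synthetic_ref, synthetic_guides):
        """total_r and reference_ratio are invariant in expectation under
        uniform equal-rate subsampling of both libraries."""
        truth = u.simulate_alleles(synthetic_ref, synthetic_guides, seed=9)
        counts, nd, nr = u.simulate_counts(truth, seed=9)
        full = u.UtrDeletionScreen.from_count_table(counts, nd, nr, synthetic_ref)
        full_res = full.fit(seed=0, compute_ci=False)
        rng = np.random.default_rng(1)
        rate = 0.5
        sub = counts.copy()
        sub["dna_count"] = rng.binomial(counts["dna_count"], rate)
        sub["rna_count"] = rng.binomial(counts["rna_count"], rate)
        submodel = u.UtrDeletionScreen.from_count_table(
            sub, int(nd * rate), int(nr * rate), synthetic_ref
        )
        sub_res = submodel.fit(seed=0, compute_ci=False)
        assert sub_res.reference_ratio == pytest.approx(full_res.reference_ratio, rel=0.05)
        assert sub_res.total_r == pytest.approx(full_res.total_r, rel=0.05)


class TestPilotClassification:
    element = u.Interval(100, 120)

    def test_class_assignment(self):
        assert classify_deletion(u.Interval(105, 110), self.element) == CLASS_INSIDE
        assert classify_deletion(u.Interval(95, 130), self.element) == CLASS_SUPERSET
        assert classify_deletion(u.Interval(10, 20), self.element) == CLASS_CONTROL
        # straddles one boundary: belongs to no class
        assert classify_deletion(u.Interval(95, 110), self.element) is None
        assert classify_deletion(u.Interval(110, 130), self.element) is None
        # the element itself counts as fully inside
        assert classify_deletion(self.element, self.element) == CLASS_INSIDE

    def _dels(self, inside_vals, superset_vals, control_vals):
        dels = []
        for i, v in enumerate(inside_vals):
            dels.append(
                DistinctDeletion(102 + i, 5, dna_count=100 - i,
                                 rna_count=1, normalized_r=v, retained=True)
            )
        for i, v in enumerate(superset_vals):
            dels.append(
                DistinctDeletion(95 - i, 30 + 2 * i, dna_count=100 - i,
                                 rna_count=1, normalized_r=v, retained=True)
            )
        for i, v in enumerate(control_vals):
            dels.append(
                DistinctDeletion(10 + i, 5, dna_count=100 - i, rna_count=1,
                                 normalized_r=v, retained=True)
            )
        return dels

    def test_perfect_separation_exact_p(self):
        """All 9 inside-ratios above all 9 control-ratios: the exact two-sided
        Mann-Whitney p is 2 / C(18, 9)."""
        inside = [2.0 + 0.01 * i for i in range(9)]
        superset = [1.8 + 0.013 * i for i in range(9)]
        control = [1.0 + 0.011 * i for i in range(9)]
        res = u.pilot_class_analysis(self._dels(inside, superset, control), self.element)
        expected = 2 / comb(18, 9)
        assert res.p_inside_vs_control == pytest.approx(expected, rel=1e-9)
        assert res.p_superset_vs_control == pytest.approx(expected, rel=1e-9)

    def test_top_n_selected_by_dna_count(self):
        inside = [2.0 + 0.01 * i for i in range(12)]
        res = u.pilot_class_analysis(
            self._dels(inside, [1.5, 1.51, 1.52], [1.0, 1.01, 1.02]),
            self.element,
        )
        # the 9 most DNA-abundant inside-deletions are the first 9 constructed
        assert sorted(res.values[CLASS_INSIDE]) == sorted(inside[:9])

    def test_small_class_is_error(self):
        dels = self._dels([2.0, 2.01], [1.5, 1.51, 1.52], [1.0, 1.01, 1.02])
        with pytest.raises(ValueError, match="fewer than 3"):
            u.pilot_class_analysis(dels, self.element)

    def test_null_rejection_rate_near_alpha(self):
        """Classes drawn from one distribution: the 9v9 comparison rejects at
        roughly the nominal rate (discrete exact test, slightly conservative)."""
        rng = np.random.default_rng(3)
        reps, hits = 400, 0
        for _ in range(reps):
            vals = rng.lognormal(0, 0.3, size=27)
            res = u.pilot_class_analysis(
                self._dels(vals[:9], vals[9:18], vals[18:]), self.element
            )
            hits += res.p_inside_vs_control <= 0.05
        rate = hits / reps
        assert 0.01 <= rate <= 0.085


def test_from_count_table_round_trip(synthetic_ref, synthetic_guides):
    truth = u.simulate_alleles(synthetic_ref, synthetic_guides, seed=2)
    counts, nd, nr = u.simulate_counts(truth, seed=2)
    dels, summary = u.quantify.from_count_table(counts, nd, nr)
    assert summary.dna_total == nd
    assert sum(d.dna_count for d in dels) + summary.dna_reference == nd
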