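"""Synthetic-screen generator: allele model, read emission, effect encoding."""

import numpy as np
import pysam
import pytest

import utrdissect as u


class TestEffectProfile:
    def test_multiplier_composition(self):
        prof = u.EffectProfile(
            regions=[u.EffectRegion(10, 20, 2.0), u.EffectRegion(30, 40, 0.5)]
        )
        assert prof.multiplier_for(u.Interval(12, 15)) == 2.0
        assert prof.multiplier_for(u.Interval(25, 28)) == 1.0
        assert prof.multiplier_for(u.Interval(15, 35)) == 1.0  # 2.0 * 0.5
        assert prof.multiplier_for(None) == 1.0

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            u.EffectProfile(regions=[u.EffectRegion(10, 20, 2.0), u.EffectRegion(15, 25, 0.5)])

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            u.EffectProfile(regions=[u.EffectRegion(10, 20, 0.0)])


class TestSimulateAlleles:
    def test_forced_dual_cut(self, synthetic_ref, synthetic_guides):
        two = [synthetic_guides[3], synthetic_guides[40]]
        truth = u.simulate_alleles(
            synthetic_ref,
            two,
            params=u.AlleleParams(dual_cut_probability=1.0, n_draws=50),
            seed=0,
        )
        dels = [a for a in truth.alleles if a.deletion is not None]
        assert len(dels) == 1
        c1, c2 = sorted(g.cut_position for g in two)
        assert dels[0].deletion == u.Interval(c1, c2)
        assert any(a.deletion is None for a in truth.alleles)

    def test_intact_only(self, synthetic_ref, synthetic_guides):
        truth = u.simulate_alleles(
            synthetic_ref,
            synthetic_guides,
            params=u.AlleleParams(intact_fraction=1.0),
            seed=0,
        )
        assert len(truth.alleles) == 1
        assert truth.alleles[0].deletion is None
        assert truth.alleles[0].dna_freq == 1.0

    def test_bad_intact_fraction(self, synthetic_ref, synthetic_guides):
        with pytest.raises(ValueError, match="intact_fraction"):
            u.simulate_alleles(
                synthetic_ref,
                synthetic_guides,
                params=u.AlleleParams(intact_fraction=0.0),
            )

    def test_seed_reproducibility(self, synthetic_ref, synthetic_guides):
        a = u.simulate_alleles(synthetic_ref, synthetic_guides, seed=12)
        b = u.simulate_alleles(synthetic_ref, synthetic_guides, seed=12)
        assert a.truth_frame().equals(b.truth_frame())

    def test_frequencies_sum_to_one(self, synthetic_ref, synthetic_guides):
        truth = u.simulate_alleles(synthetic_ref, synthetic_guides, seed=3)
        assert truth.dna_freqs.sum() == pytest.approx(1.0)

    def test_alleles_touch_a_cut_site(self, synthetic_ref, synthetic_guides):
        truth = u.simulate_alleles(synthetic_ref, synthetic_guides, seed=4)
        cuts = {g.cut_position for g in synthetic_guides}
        for a in truth.alleles:
            if a.deletion is None:
                continue
            assert any(a.deletion.start <= c <= a.deletion.end for c in cuts)

    def test_rna_rel_encodes_effect(self, synthetic_ref, synthetic_guides):
        prof = u.EffectProfile(regions=[u.EffectRegion(560, 580, 2.0)], baseline_ratio=0.8)
        truth = u.simulate_alleles(synthetic_ref, synthetic_guides, profile=prof, seed=5)
        for a in truth.alleles:
            expected = a.dna_freq * 0.8 * prof.multiplier_for(a.deletion)
            assert a.rna_rel == pytest.approx(expected)


class TestSimulateReads:
    def _truth(self, ref, guides, **kwargs):
        params = kwargs.pop("params", None)
        return u.simulate_alleles(ref, guides, params=params, seed=1, **kwargs)

    def test_intact_reads_are_all_matches(self, tmp_path, synthetic_ref, synthetic_guides):
        truth = self._truth(
            synthetic_ref,
            synthetic_guides,
            params=u.AlleleParams(intact_fraction=1.0),
            reads=u.ReadParams(dna_fragments=50, rna_fragments=50, error_rate=0.0),
        )
        out = u.simulate_reads(truth, tmp_path)
        with pysam.AlignmentFile(str(out.dna_sam), "r") as sam:
            cigars = {rec.cigarstring for rec in sam}
        assert cigars == {"150M"}

    def test_junction_reads_show_one_deletion(self, tmp_path, synthetic_ref, synthetic_guides):
        two = [synthetic_guides[10], synthetic_guides[11]]
        truth = u.simulate_alleles(
            synthetic_ref,
            two,
            params=u.AlleleParams(
                dual_cut_probability=0.0, n_draws=1, intact_fraction=0.01,
                length_mode=10, length_decay=1e-9, max_length=10,
            ),
            seed=2,
            reads=u.ReadParams(dna_fragments=300, rna_fragments=10, error_rate=0.0),
        )
        dels = [a.deletion for a in truth.alleles if a.deletion is not None]
        assert len(dels) == 1 and len(dels[0]) == 10
        out = u.simulate_reads(truth, tmp_path)
        seen_d = 0
        with pysam.AlignmentFile(str(out.dna_sam), "r") as sam:
            for rec in sam:
                d_ops = [ln for op, ln in rec.cigartuples if op == 2]
                assert len(d_ops) <= 1
                if d_ops:
                    assert d_ops == [10]
                    seen_d += 1
        assert seen_d > 0

    def test_fragment_conservation_and_truth_table(self, tmp_path, synthetic_ref, synthetic_guides):
        truth = self._truth(
            synthetic_ref,
            synthetic_guides,
            reads=u.ReadParams(dna_fragments=120, rna_fragments=80),
        )
        out = u.simulate_reads(truth, tmp_path)
        assert (out.fragments.library == "DNA").sum() == 120
        assert (out.fragments.library == "RNA").sum() == 80
        for path, n in ((out.dna_fastq1, 120), (out.rna_fastq2, 80)):
            lines = path.read_text().splitlines()
            assert len(lines) == 4 * n

    def test_sam_fastq_sequences_agree(self, tmp_path, synthetic_ref, synthetic_guides):
        from Bio.Seq import Seq

        truth = self._truth(
            synthetic_ref,
            synthetic_guides,
            reads=u.ReadParams(dna_fragments=30, rna_fragments=5),
        )
        out = u.simulate_reads(truth, tmp_path)
        fastq2 = {}
        lines = out.dna_fastq2.read_text().splitlines()
        for i in range(0, len(lines), 4):
            fastq2[lines[i][1:].split("/")[0]] = lines[i + 1]
        with pysam.AlignmentFile(str(out.dna_sam), "r") as sam:
            for rec in sam:
                if rec.is_read2:
                    # SAM stores reference orientation; FASTQ the sequenced strand
                    assert (
                        str(Seq(rec.query_sequence).reverse_complement())
                        == fastq2[rec.query_name]
                    )

    def test_error_free_ratio_recovery(self, synthetic_ref, synthetic_guides):
        """With all multipliers 1 and equal depths, each well-covered allele's
        empirical r sits within 3 binomial standard errors of baseline_ratio."""
        truth = u.simulate_alleles(
            synthetic_ref, synthetic_guides, params=u.AlleleParams(n_draws=30), seed=6
        )
        depth = 100_000
        counts, nd, nr = u.simulate_counts(truth, seed=6, dna_fragments=depth, rna_fragments=depth)
        baseline = truth.profile.baseline_ratio  # 1.0
        freqs = truth.truth_frame()["dna_freq"].to_numpy()
        checked = 0
        for row, f in zip(counts.itertuples(index=False), freqs):
            expect = depth * f
            if expect < 200:
                continue
            r_hat = row.rna_count / row.dna_count
            # binomial SE on each count, propagated to the ratio
            se = baseline * np.sqrt(2.0 * (1 - f) / expect)
            assert abs(r_hat - baseline) <= 3 * se
            checked += 1
        assert checked >= 3
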