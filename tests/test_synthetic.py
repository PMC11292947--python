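"""Generator determinism, planted structure and observation model."""

import numpy as np
import pandas as pd
import pytest

from mosaicmeth import synthetic as syn
from mosaicmeth.core import UNMETHYLATED_SPIKE, global_mcg, nonconversion_rate


class TestGenerateGenome:
    def test_deterministic_for_seed(self):
        a = syn.generate_genome(n_contigs=1, contig_length=50_000, n_genes=10, n_tes=6, seed=5)
        b = syn.generate_genome(n_contigs=1, contig_length=50_000, n_genes=10, n_tes=6, seed=5)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1].genes, b[1].genes)
        pd.testing.assert_frame_equal(a[2].intervals, b[2].intervals)

    def test_no_tes_gives_empty_regionset(self):
        _, _, tes, _ = syn.generate_genome(n_contigs=1, contig_length=50_000,
                                           n_genes=10, n_tes=0, seed=5)
        assert len(tes) == 0

    def test_te_lengths_straddle_400bp_filter(self):
        from mosaicmeth.te_umr import filter_and_classify_tes
        seqs, ann, tes, _ = syn.generate_genome(
            n_contigs=1, contig_length=200_000, n_genes=20, n_tes=20, seed=5,
            te_length=[200, 600])
        lengths = (tes.intervals["end"] - tes.intervals["start"]).unique()
        assert set(lengths) == {200, 600}
        truth = syn.make_truth(seqs, ann, tes, seed=5)
        meth = syn.generate_methylome(truth, "gastrula", mean_depth=30, seed=6)
        kept = filter_and_classify_tes(tes, ann, meth)
        assert (kept["length"] == 600).all()

    def test_sizing_error_when_genes_do_not_fit(self):
        with pytest.raises(syn.SizingError):
            syn.generate_genome(n_contigs=1, contig_length=20_000, n_genes=50, n_tes=0, seed=1)

    def test_genes_non_overlapping_and_exons_valid(self, small_world):
        genes = small_world["annotation"].genes
        for contig, sub in genes.groupby("contig"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


class TestExpression:
    def test_truth_matrix_nonexpressed_fraction(self, small_world):
        truth = small_world["truth"]
        expr = syn.generate_expression(truth)
        frac = (expr.mean(axis=1) < 1).mean()
        assert 0.03 < frac < 0.33  # planted 0.10 plus low-mean tail, n=60

    def test_cv_zero_gives_constant_genes(self, small_world):
        expr = syn.generate_expression(small_world["truth"], seed=3,
                                       stages=("a", "b", "c"), cv=0.0)
        assert (expr.nunique(axis=1) == 1).all()

    def test_deterministic_for_seed(self, small_world):
        a = syn.generate_expression(small_world["truth"], seed=4, stages=("a", "b"))
        b = syn.generate_expression(small_world["truth"], seed=4, stages=("a", "b"))
        pd.testing.assert_frame_equal(a, b)


class TestGenerateMethylome:
    def test_deterministic_and_zero_depth_omitted(self, small_world):
        truth = small_world["truth"]
        a = syn.generate_methylome(truth, "adult", mean_depth=1.0, seed=9)
        b = syn.generate_methylome(truth, "adult", mean_depth=1.0, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert (a.records["n_total"] >= 1).all()
        n_sites = sum(len(v) for v in truth.cpg_positions.values())
        assert len(a.context("CG")) < n_sites  # Poisson(1) leaves ~37% uncovered

    def test_erosion_halves_global_level(self, small_world):
        truth = small_world["truth"]
        full = syn.generate_methylome(truth, "gastrula", 20, seed=1,
                                      include_spikes=False, include_non_cg=False)
        half = syn.generate_methylome(truth, "gastrula", 20, seed=2, erosion_factor=0.5,
                                      include_spikes=False, include_non_cg=False)
        g1 = global_mcg(full, min_total=0).fraction
        g2 = global_mcg(half, min_total=0).fraction
        assert g2 == pytest.approx(g1 / 2, rel=0.05)

    def test_spike_in_reports_nonconversion(self, small_world):
        meth = small_world["methylome"]
        rates = nonconversion_rate(meth)
        assert rates["spike_unmeth"] == pytest.approx(0.01, abs=0.006)
        assert rates["spike_meth_excess"] == pytest.approx(0.005, abs=0.006)
        assert rates["non_cpg"] == pytest.approx(0.01, abs=0.006)

    def test_expected_gbm_matches_targets_where_unobstructed(self, small_world):
        truth = small_world["truth"]
        exp = truth.expected_gbm("gastrula")
        assert exp.between(0, 1).all()


class TestDepletion:
    def test_fraction_zero_is_identity(self, small_world):
        m = small_world["methylome"]
        out = syn.apply_global_depletion(m, 0.0, seed=1)
        pd.testing.assert_frame_equal(
            out.records.reset_index(drop=True), m.records.reset_index(drop=True))

    def test_fraction_one_zeroes_methylation(self, small_world):
        out = syn.apply_global_depletion(small_world["methylome"], 1.0, seed=1)
        assert (out.records["n_meth"] == 0).all()
        assert out.records["n_total"].equals(small_world["methylome"].records["n_total"])

    def test_partial_depletion_scales_global_level(self, small_world):
        m = small_world["methylome"]
        base = global_mcg(m, min_total=0).fraction
        dep = syn.apply_global_depletion(m, 0.042, seed=2)
        got = global_mcg(dep, min_total=0).fraction
        assert got == pytest.approx(base * (1 - 0.042), rel=0.01)


class TestSkimming:
    def test_total_counts_near_requested_reads(self, small_world):
        series = syn.generate_skimming_series(small_world["truth"],
                                              reads_per_sample=5000, seed=3)
        for reps in series.values():
            for m in reps:
                total = m.records["n_total"].sum()
                assert abs(total - 5000) < 4 * np.sqrt(5000)

    def test_global_estimates_decrease_with_age_in_expectation(self, small_world):
        truth = small_world["truth"]
        expected = [truth.expected_global(erosion_factor=f)
                    for f in truth.age_erosion.values()]
        assert all(b < a for a, b in zip(expected, expected[1:]))

    def test_deterministic_for_seed(self, small_world):
        a = syn.generate_skimming_series(small_world["truth"], reads_per_sample=2000, seed=7)
        b = syn.generate_skimming_series(small_world["truth"], reads_per_sample=2000, seed=7)
        for age in a:
            pd.testing.assert_frame_equal(a[age][0].records, b[age][0].records)

    def test_requires_strictly_decreasing_age_factors(self, small_world):
        with pytest.raises(ValueError):
            syn.generate_skimming_series(
                small_world["truth"], ages=["senescent_22w", "larva_st8"],
                reads_per_sample=100, seed=1)


class TestTruthInvariants:
    def test_erosion_must_be_non_increasing(self, small_world):
        w = small_world
        with pytest.raises(ValueError, match="non-increasing"):
            syn.make_truth(w["sequences"], w["annotation"], w["tes"], seed=1,
                           stages=("a", "b"), erosion=(0.5, 0.9))

    def test_planted_dmrs_satisfy_callability(self):
        seqs, ann, tes, _ = syn.generate_genome(
            n_contigs=1, contig_length=400_000, n_genes=30, n_tes=10, seed=3,
            gene_length=(1000, 2000), min_gap=3000)
        truth = syn.make_truth(seqs, ann, tes, seed=3, n_dmrs=10)
        assert (truth.dmrs["n_cpgs"] >= 5).all()
        levels = np.vstack([truth.dmr_levels[s] for s in truth.stages])
        assert (np.ptp(levels, axis=0) >= 0.2).all()
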