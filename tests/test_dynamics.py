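"""Twofold GbM-change rule, DMR calling, region annotation, depletion, aging."""

import numpy as np
import pandas as pd
import pytest

from mosaicmeth.dynamics import (
    aging_trajectory,
    annotate_regions,
    call_dmrs,
    compare_depletion,
    detect_gbm_changes,
)
from mosaicmeth.io_formats import RegionSet

from conftest import make_annotation, make_methylome


def _gbm(values):
    df = pd.DataFrame({"gbm": values}, index=[f"g{i}" for i in range(len(values))])
    df["passed"] = True
    return df


class TestTwofoldRule:
    def test_uniform_shift_is_all_stable(self):
        a = _gbm([0.3, 0.5, 0.7])
        b = _gbm([0.25, 0.45, 0.65])
        calls = detect_gbm_changes(a, b)
        assert (calls["call"] == "stable").all()

    def test_rule_arithmetic_example(self):
        # global mean difference -0.05; a gene at -0.20 deviates by 0.15 > 0.10
        a = _gbm([0.5] * 10)
        diffs = [-0.05] * 9 + [-0.20]
        b = _gbm([0.5 + d for d in diffs])
        calls = detect_gbm_changes(a, b)
        assert calls["global_mean_difference"].iloc[0] == pytest.approx(-0.065)
        # with d_bar = -0.065 the planted gene deviates by 0.135 > 0.13
        assert calls.loc["g9", "call"] == "hypomethylated"
        assert (calls.drop("g9")["call"] == "stable").all()

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.2, 0.8, 200)
        diff = rng.normal(-0.05, 0.02, 200)
        a = _gbm(list(base))
        b1 = _gbm(list(base + diff))
        b2 = _gbm(list(base + diff + 0.1))
        c1 = detect_gbm_changes(a, b1)["call"]
        c2 = detect_gbm_changes(a, b2)["call"]
        assert (c1 == c2).all()

    def test_zero_mean_falls_back_to_absolute(self):
        a = _gbm([0.4, 0.4])
        b = _gbm([0.4, 0.4])
        calls = detect_gbm_changes(a, b)
        assert calls["absolute_fallback"].all()
        assert (calls["call"] == "stable").all()


class TestDMRCaller:
    def test_identical_samples_give_zero_dmrs(self, small_world):
        m = small_world["methylome"]
        assert call_dmrs(m, m) == []

    def test_planted_block_called_once_with_direction(self):
        pos = list(range(100, 300, 20))  # 10 CpGs in 200 bp
        high = make_methylome([("c", p, "+", "CG", 16, 20) for p in pos], "A")
        low = make_methylome([("c", p, "+", "CG", 2, 20) for p in pos], "B")
        calls = call_dmrs(high, low)
        assert len(calls) == 1
        d = calls[0]
        assert d.direction == "hypo" and d.n_cpgs == 10
        assert d.mean_difference == pytest.approx(-0.7)
        assert d.start == 99 and d.end == 281

    def test_four_seed_cpgs_not_called(self):
        pos = [100, 120, 140, 160]
        a = make_methylome([("c", p, "+", "CG", 18, 20) for p in pos], "A")
        b = make_methylome([("c", p, "+", "CG", 2, 20) for p in pos], "B")
        assert call_dmrs(a, b) == []

    def test_low_coverage_cpgs_excluded(self):
        pos = list(range(100, 300, 20))
        a = make_methylome([("c", p, "+", "CG", 3, 3) for p in pos], "A")
        b = make_methylome([("c", p, "+", "CG", 0, 3) for p in pos], "B")
        assert call_dmrs(a, b, min_cov=4) == []

    def test_merge_distance_splits_far_seeds(self):
        pos = list(range(100, 200, 20)) + list(range(600, 700, 20))  # gap 400 bp
        a = make_methylome([("c", p, "+", "CG", 18, 20) for p in pos], "A")
        b = make_methylome([("c", p, "+", "CG", 2, 20) for p in pos], "B")
        calls = call_dmrs(a, b)
        assert len(calls) == 2


class TestAnnotateRegions:
    @pytest.fixture()
    def setup(self):
        ann = make_annotation(
            [("g1", "c", "+", 10_000, 13_000)],
            exons={"g1": [(10_000, 11_000), (12_000, 13_000)]},
            contig_lengths={"c": 50_000})
        atac = RegionSet(pd.DataFrame(
            [("c", 30_000, 30_400, "peak1")], columns=["contig", "start", "end", "label"]))
        tes = RegionSet(pd.DataFrame(
            [("c", 11_200, 11_700, "te1")], columns=["contig", "start", "end", "label"]))
        return ann, atac, tes

    def _df(self, rows):
        return pd.DataFrame(rows, columns=["contig", "start", "end"])

    def test_promoter_beats_exon(self, setup):
        ann, atac, tes = setup
        out = annotate_regions(self._df([("c", 9500, 10_200)]), ann, atac, tes)
        assert out["category"].iloc[0] == "promoter"

    def test_atac_outside_promoter_is_distal(self, setup):
        ann, atac, tes = setup
        out = annotate_regions(self._df([("c", 30_100, 30_200)]), ann, atac, tes)
        assert out["category"].iloc[0] == "distal_regulatory"

    def test_intron_with_te_flag(self, setup):
        ann, atac, tes = setup
        out = annotate_regions(self._df([("c", 11_300, 11_600)]), ann, atac, tes)
        assert out["category"].iloc[0] == "intron"
        assert bool(out["contains_te"].iloc[0])

    def test_unknown_contig_unplaced(self, setup):
        ann, atac, tes = setup
        with pytest.warns(UserWarning, match="unknown contig"):
            out = annotate_regions(self._df([("weird", 0, 100)]), ann, atac, tes)
        assert out["category"].iloc[0] == "unplaced"

    def test_every_region_gets_exactly_one_category(self, setup):
        ann, atac, tes = setup
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 49_000, 50)
        out = annotate_regions(
            self._df([("c", int(s), int(s) + 200) for s in starts]), ann, atac, tes)
        assert out["category"].notna().all()
        assert set(out["category"]).issubset(
            {"promoter", "exon", "intron", "distal_regulatory", "intergenic"})


class TestDepletionComparison:
    def test_identical_arms_zero_depletion(self, small_world):
        m = small_world["methylome"]
        res = compare_depletion([m, m], [m, m])
        assert res["relative_depletion"] == pytest.approx(0.0)
        assert np.isnan(res["p"]) or res["p"] > 0.9  # zero variance

    def test_single_replicate_skips_test(self, small_world):
        m = small_world["methylome"]
        res = compare_depletion([m], [m])
        assert not res["tested"] and np.isnan(res["p"])
        assert res["difference_pp"] == pytest.approx(0.0)


class TestAgingTrajectory:
    def test_single_shallow_sample_equals_read_fraction(self):
        m = make_methylome([("c", p, "+", "CG", x, 1) for p, x in
                            [(10, 1), (20, 0), (30, 1), (40, 0), (50, 0)]])
        df = aging_trajectory({"young": [m]})
        assert df["global_mcg"].iloc[0] == pytest.approx(0.4)

    def test_constant_truth_not_flagged_monotone(self, small_world):
        from mosaicmeth import synthetic as syn
        truth = small_world["truth"]
        reps = {f"a{i}": [syn.generate_methylome(truth, "adult", 0.3, seed=100 + i,
                                                 include_spikes=False, include_non_cg=False)]
                for i in range(4)}
        df = aging_trajectory(reps)
        # same condition at shallow depth: estimates jitter, not monotone
        assert not df["monotone_decreasing"].iloc[0]

    def test_decreasing_series_flagged(self, small_world):
        from mosaicmeth import synthetic as syn
        series = syn.generate_skimming_series(small_world["truth"],
                                              reads_per_sample=20_000, seed=5)
        df = aging_trajectory(series)
        assert df["monotone_decreasing"].iloc[0]
        assert ((df["ci_low"] <= df["global_mcg"]) & (df["global_mcg"] <= df["ci_high"])).all()
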