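"""TE filtering/methylation, TE differential expression, UMR segmentation."""

import numpy as np
import pandas as pd
import pytest

from mosaicmeth.io_formats import RegionSet
from mosaicmeth.te_umr import (
    UMR,
    call_umrs,
    compare_umr_sizes,
    filter_and_classify_tes,
    gbm_by_intron_te_strata,
    promoter_umr_summary,
    te_differential_expression,
)

from conftest import make_annotation, make_methylome


def _regions(rows):
    return RegionSet(pd.DataFrame(rows, columns=["contig", "start", "end", "label"]))


class TestTEFilterAndClassify:
    def test_length_filter_is_strict(self):
        ann = make_annotation([("g1", "c", "+", 10_000, 12_000)])
        tes = _regions([("c", 0, 400, "te400#LTR"), ("c", 1000, 1401, "te401#LTR")])
        meth = make_methylome([("c", p, "+", "CG", 5, 10) for p in range(1001, 1401, 50)])
        out = filter_and_classify_tes(tes, ann, meth)
        assert list(out["label"]) == ["te401#LTR"]

    def test_any_gene_overlap_is_genic(self):
        ann = make_annotation([("g1", "c", "+", 10_000, 12_000)])
        tes = _regions([("c", 11_800, 12_500, "bridge#LINE"),
                        ("c", 20_000, 20_600, "far#LINE")])
        meth = make_methylome([("c", p, "+", "CG", 5, 10) for p in range(11_801, 20_601, 40)])
        out = filter_and_classify_tes(tes, ann, meth).set_index("label")
        assert out.loc["bridge#LINE", "location"] == "genic"
        assert out.loc["far#LINE", "location"] == "intergenic"

    def test_methylation_fraction_and_status(self):
        ann = make_annotation([("g1", "c", "+", 50_000, 52_000)])
        tes = _regions([("c", 1000, 1600, "te#DNA")])
        rows = [("c", 1100 + i * 40, "+", "CG", m, 10) for i, m in
                enumerate([8, 2, 8, 2, 5, 5])]
        out = filter_and_classify_tes(tes, ann, make_methylome(rows))
        assert out["methylation"].iloc[0] == pytest.approx(0.5)
        assert out["status"].iloc[0] == "methylated"

    def test_uncovered_te_undefined(self):
        ann = make_annotation([("g1", "c", "+", 50_000, 52_000)])
        tes = _regions([("c", 1000, 1600, "te#DNA")])
        out = filter_and_classify_tes(tes, ann, make_methylome([("c", 90_000, "+", "CG", 1, 8)]))
        assert out["status"].iloc[0] == "undefined" and np.isnan(out["methylation"].iloc[0])

    def test_location_classes_partition(self, small_world):
        out = filter_and_classify_tes(small_world["tes"], small_world["annotation"],
                                      small_world["methylome"])
        assert set(out["location"]) <= {"genic", "intergenic"}
        assert out["location"].notna().all()


class TestIntronTEStrata:
    def test_stratum_assignment(self):
        ann = make_annotation(
            [("g1", "c", "+", 0, 4000)],
            exons={"g1": [(0, 500), (1500, 2000), (2500, 3000), (3500, 4000)]})
        tes = _regions([("c", 600, 1100, "te1#LTR"), ("c", 3050, 3460, "te2#LTR")])
        gbm = pd.DataFrame({"gbm": [0.5], "passed": [True]}, index=["g1"])
        strata, _ = gbm_by_intron_te_strata(gbm, ann, tes)
        assert strata.loc["g1", "n_introns"] == 3
        assert strata.loc["g1", "n_te_introns"] == 2

    def test_te_methylating_mode_raises_gbm_of_te_genes(self):
        from mosaicmeth import synthetic as syn
        from mosaicmeth.gbm import gene_body_methylation
        seqs, ann, tes, _ = syn.generate_genome(
            n_contigs=2, contig_length=500_000, n_genes=150, n_tes=120, seed=21,
            gene_length=(1500, 3000), min_gap=800, te_length=(420, 900))
        truth = syn.make_truth(seqs, ann, tes, seed=21, expression_link=False,
                               cv_link=False, te_mode=True, te_level=0.85)
        meth = syn.generate_methylome(truth, "gastrula", 30, seed=22)
        gbm = gene_body_methylation(meth, ann)
        strata, comp = gbm_by_intron_te_strata(gbm, ann, tes)
        assert len(comp) > 0
        assert (comp["median_with_te"] > comp["median_without_te"]).all()

    def test_no_te_targeting_no_difference(self):
        from mosaicmeth import synthetic as syn
        from mosaicmeth.gbm import gene_body_methylation
        seqs, ann, tes, _ = syn.generate_genome(
            n_contigs=2, contig_length=500_000, n_genes=150, n_tes=120, seed=23,
            gene_length=(1500, 3000), min_gap=800, te_length=(420, 900))
        truth = syn.make_truth(seqs, ann, tes, seed=23, expression_link=False,
                               cv_link=False, te_mode=False)
        meth = syn.generate_methylome(truth, "gastrula", 30, seed=24)
        gbm = gene_body_methylation(meth, ann)
        _, comp = gbm_by_intron_te_strata(gbm, ann, tes)
        assert (comp["p"] > 0.01).all()


class TestTEDifferentialExpression:
    def test_identical_groups_no_calls(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(4, 1, 300)
        counts = pd.DataFrame({"a1": rng.poisson(mu), "a2": rng.poisson(mu),
                               "b1": rng.poisson(mu), "b2": rng.poisson(mu)},
                              index=[f"TE{i}" for i in range(300)])
        res = te_differential_expression(counts, {"a1": "c", "a2": "c",
                                                  "b1": "z", "b2": "z"})
        assert (res["call"] == "ns").all()

    def test_planted_eightfold_up_tes_recovered(self):
        rng = np.random.default_rng(2)
        n = 500
        mu = rng.lognormal(4, 1, n)
        mu_t = mu.copy()
        up = set(rng.choice(n, 50, replace=False))
        for i in up:
            mu_t[i] *= 8
        counts = pd.DataFrame({"c1": rng.poisson(mu), "c2": rng.poisson(mu),
                               "z1": rng.poisson(mu_t), "z2": rng.poisson(mu_t)},
                              index=[f"TE{i}" for i in range(n)])
        res = te_differential_expression(counts, {"c1": "c", "c2": "c",
                                                  "z1": "z", "z2": "z"})
        called = set(int(i[2:]) for i in res[res["call"] == "up"].index)
        assert len(called & up) >= 45  # >= 90% sensitivity
        assert len(called - up) == 0

    def test_intergenic_share_of_calls_tracked(self):
        # 40 planted up-TEs, 34 of them (85%) intergenic
        rng = np.random.default_rng(3)
        n = 400
        mu = rng.lognormal(5, 0.5, n)
        mu_t = mu.copy()
        up = list(range(40))
        for i in up:
            mu_t[i] *= 10
        counts = pd.DataFrame({"c1": rng.poisson(mu), "c2": rng.poisson(mu),
                               "z1": rng.poisson(mu_t), "z2": rng.poisson(mu_t)},
                              index=[f"TE{i}" for i in range(n)])
        location = ["intergenic"] * n
        for i in list(range(34, 40)) + list(range(200, 280)):
            location[i] = "genic"
        te_table = pd.DataFrame({"label": [f"TE{i}" for i in range(n)],
                                 "location": location, "family": "LTR"})
        res = te_differential_expression(counts, {"c1": "c", "c2": "c",
                                                  "z1": "z", "z2": "z"},
                                         te_table=te_table)
        ct = res.attrs["location_crosstab"]
        share = ct.loc["up", "intergenic"] / ct.loc["up"].sum()
        assert share == pytest.approx(0.85, abs=0.05)

    def test_all_zero_rows_dropped_and_counted(self):
        counts = pd.DataFrame({"a1": [0, 5], "a2": [0, 6], "b1": [0, 4], "b2": [0, 7]},
                              index=["dead", "alive"])
        res = te_differential_expression(counts, {"a1": "c", "a2": "c",
                                                  "b1": "z", "b2": "z"})
        assert res.attrs["n_all_zero"] == 1 and list(res.index) == ["alive"]


class TestUMRs:
    def test_fully_methylated_genome_no_umrs(self):
        rows = [("c", p, "+", "CG", 9, 10) for p in range(100, 2000, 25)]
        assert call_umrs(make_methylome(rows)) == []

    def test_planted_low_run_called_exactly(self):
        rows = ([("c", p, "+", "CG", 8, 10) for p in range(100, 400, 30)]
                + [("c", p, "+", "CG", 0, 10) for p in range(400, 700, 30)]
                + [("c", p, "+", "CG", 8, 10) for p in range(700, 1000, 30)])
        umrs = call_umrs(make_methylome(rows))
        assert len(umrs) == 1
        u = umrs[0]
        assert u.n_cpgs == 10 and u.start == 399 and u.end == 671
        assert u.mean_methylation == pytest.approx(0.0)

    def test_three_low_cpgs_not_called(self):
        rows = ([("c", p, "+", "CG", 9, 10) for p in (100, 130, 160)]
                + [("c", p, "+", "CG", 0, 10) for p in (200, 230, 260)]
                + [("c", p, "+", "CG", 9, 10) for p in (300, 330, 360)])
        assert call_umrs(make_methylome(rows)) == []

    def test_umrs_disjoint_sorted_and_maximal(self, small_world):
        umrs = call_umrs(small_world["methylome"])
        for a, b in zip(umrs, umrs[1:]):
            if a.contig == b.contig:
                assert a.end <= b.start  # disjoint and sorted
        # maximality: every called run is bounded by >= cutoff CpGs or data edge
        assert all(u.n_cpgs >= 4 for u in umrs)

    def test_low_coverage_sites_ignored(self):
        rows = [("c", p, "+", "CG", 0, 2) for p in range(100, 400, 30)]
        assert call_umrs(make_methylome(rows), min_cov=4) == []


class TestPromoterUMRSummary:
    def _ann(self):
        return make_annotation([("g1", "c", "+", 10_000, 12_000)],
                               contig_lengths={"c": 100_000})

    def test_all_promoter_umrs_fraction_one(self):
        umrs = [UMR("c", 9000, 9800, 10, 0.01), UMR("c", 8200, 8900, 8, 0.02)]
        out = promoter_umr_summary(umrs, self._ann())
        assert out["promoter_fraction"] == 1.0

    def test_size_5000_excluded_strictly(self):
        umrs = [UMR("c", 9000, 14_000, 60, 0.01),   # size exactly 5000
                UMR("c", 9000, 9999, 12, 0.01)]
        out = promoter_umr_summary(umrs, self._ann())
        assert out["n_excluded_by_size"] == 1 and out["n_umrs"] == 1

    def test_size_comparison_between_datasets(self):
        rng = np.random.default_rng(9)
        a = {"promoter_sizes": rng.normal(2000, 200, 200), "other_sizes": np.array([])}
        b = {"promoter_sizes": rng.normal(1200, 200, 200), "other_sizes": np.array([])}
        res = compare_umr_sizes(a, b)
        assert res["tested"] and res["p"] < 0.01 and res["median1"] > res["median2"]
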