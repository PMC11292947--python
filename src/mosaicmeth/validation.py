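"""End-to-end recovery benchmarks on synthetic methylomes.

Each function simulates a study condition with :mod:`mosaicmeth.synthetic`,
runs the corresponding estimators, and scores them against the planted
truth.  They are used both by the test suite and by the acceptance script;
all randomness descends from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic as syn
from .core import global_mcg, metagene_profile
from .dynamics import call_dmrs, compare_depletion, detect_gbm_changes
from .gbm import expression_summary, gbm_by_decile, gene_body_methylation, rank_deciles
from .te_umr import call_umrs, promoter_umr_summary, te_differential_expression, UMR
from .io_formats import MethylomeTable, METH_COLUMNS, GenomeAnnotation


def _sub(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2 ** 31 - 2 ** 20)


def gbm_recovery(seed: int = 1) -> dict:
    """Per-gene GbM and global mCG recovery on a deep 2 Mb / 1000-gene genome."""
    seqs, ann, tes, _ = syn.generate_genome(
        n_contigs=2, contig_length=1_000_000, n_genes=1000, n_tes=400,
        seed=_sub(seed, 1), gene_length=(800, 1600), min_gap=200)
    truth = syn.make_truth(seqs, ann, tes, seed=_sub(seed, 2))
    meth = syn.generate_methylome(truth, "gastrula", mean_depth=30, seed=_sub(seed, 3))
    gbm = gene_body_methylation(meth, ann)
    expected = truth.expected_gbm("gastrula")
    passed = gbm[gbm["passed"]].index
    err = (gbm.loc[passed, "gbm"] - expected.loc[passed]).abs()
    r = float(np.corrcoef(gbm.loc[passed, "gbm"], expected.loc[passed])[0, 1])
    est = global_mcg(meth)
    return {
        "r": r,
        "mae": float(err.mean()),
        "global_error_pp": abs(est.fraction - truth.expected_global("gastrula")) * 100.0,
        "global_mcg_pct": est.fraction * 100.0,
        "n_genes": int(len(passed)),
    }


def _decile_medians(gbm: pd.DataFrame, deciles: pd.Series) -> np.ndarray:
    summ = gbm_by_decile(gbm, deciles)
    summ = summ[summ["decile"] != "non_expressed"]
    return summ["median"].to_numpy()


def decile_structure(seed: int = 1) -> dict:
    """Monotone GbM across expression/CV deciles, and flatness with link off."""
    out = {}
    for link_on in (True, False):
        s0 = _sub(seed, 10 if link_on else 20)
        seqs, ann, tes, _ = syn.generate_genome(
            n_contigs=2, contig_length=1_500_000, n_genes=1500, n_tes=0,
            seed=s0, gene_length=(800, 1600), min_gap=200)
        truth = syn.make_truth(seqs, ann, tes, seed=s0 + 1, te_mode=False,
                               expression_link=link_on, cv_link=link_on)
        meth = syn.generate_methylome(truth, "gastrula", mean_depth=30, seed=s0 + 2)
        gbm = gene_body_methylation(meth, ann)
        es = expression_summary(syn.generate_expression(truth))
        expr_dec = rank_deciles(es["mean_tpm"], min_value=1.0)
        cv_dec = rank_deciles(es.loc[es["mean_tpm"] >= 1, "cv"].dropna())
        med_e = _decile_medians(gbm, expr_dec)
        med_c = _decile_medians(gbm, cv_dec)
        if link_on:
            out.update(
                expr_monotone=bool(np.all(np.diff(med_e) >= 0)),
                cv_monotone=bool(np.all(np.diff(med_c) <= 0)),
                expr_min_step=float(np.diff(med_e).min()),
                cv_max_step=float(np.diff(med_c).max()),
                n_genes=int(gbm["passed"].sum()),
            )
        else:
            for name, med in (("expr", med_e), ("cv", med_c)):
                res = stats.linregress(np.arange(len(med)), med)
                out[f"null_{name}_slope"] = float(res.slope)
                out[f"null_{name}_flat"] = bool(abs(res.slope) <= 1.96 * res.stderr)
    return out


def metagene_effect(seed: int = 1) -> dict:
    """Gene-body over intergenic-background enrichment from the metagene profile."""
    seqs, ann, tes, _ = syn.generate_genome(
        n_contigs=1, contig_length=1_000_000, n_genes=100, n_tes=50,
        seed=_sub(seed, 30), gene_length=(2000, 4000), min_gap=4000)
    truth = syn.make_truth(seqs, ann, tes, seed=_sub(seed, 31))
    meth = syn.generate_methylome(truth, "gastrula", mean_depth=30, seed=_sub(seed, 32))
    prof = metagene_profile(meth, ann)
    return {"body_intergenic_ratio": prof.body_flank_ratio(), "n_genes": len(prof.gene_ids)}


def dmr_recovery(seed: int = 1) -> dict:
    """Planted-DMR sensitivity, boundary error and null false-positive rate."""
    seqs, ann, tes, _ = syn.generate_genome(
        n_contigs=2, contig_length=1_000_000, n_genes=200, n_tes=100,
        seed=_sub(seed, 40), gene_length=(1000, 2000), min_gap=3000)
    truth = syn.make_truth(seqs, ann, tes, seed=_sub(seed, 41), n_dmrs=60, dmr_delta=0.35)
    ma = syn.generate_methylome(truth, "gastrula", mean_depth=30, seed=_sub(seed, 42))
    mb = syn.generate_methylome(truth, "larva", mean_depth=30, seed=_sub(seed, 43))
    calls = call_dmrs(ma, mb)
    planted = list(truth.dmrs.itertuples())
    recovered, boundary = 0, []
    for r in planted:
        hits = [d for d in calls if d.contig == r.contig and d.start < r.end and d.end > r.start]
        if hits:
            recovered += 1
            boundary.append(max(abs(hits[0].start - r.start), abs(hits[0].end - r.end)))
    false = [d for d in calls
             if not any(d.contig == r.contig and d.start < r.end and d.end > r.start
                        for r in planted)]
    # antisymmetry under sample swap
    flipped = call_dmrs(mb, ma)
    anti = len(flipped) == len(calls) and all(
        f.start == d.start and f.end == d.end and f.direction != d.direction
        and np.isclose(f.mean_difference, -d.mean_difference)
        for f, d in zip(flipped, calls))
    return {
        "sensitivity": recovered / len(planted),
        "mean_boundary_error_bp": float(np.mean(boundary)) if boundary else 0.0,
        "max_boundary_error_bp": int(max(boundary)) if boundary else 0,
        "false_per_mb": len(false) / 2.0,
        "antisymmetric": bool(anti),
        "n_planted": len(planted),
    }


def twofold_recovery(seed: int = 1) -> dict:
    """Recovery of 50 planted GbM-shifted genes under a -0.05 global erosion."""
    s0 = _sub(seed, 50)
    seqs, ann, tes, _ = syn.generate_genome(
        n_contigs=2, contig_length=1_000_000, n_genes=1050, n_tes=0,
        seed=s0, gene_length=(800, 1600), min_gap=200)
    base = syn.make_truth(seqs, ann, tes, seed=s0 + 1, stages=("A", "B"),
                          erosion=(1.0, 1.0), te_mode=False)
    headroom = base.gene_params[
        (base.gene_params["target_gbm"] >= 0.35) & (base.gene_params["target_gbm"] <= 0.70)
    ].index
    rng = np.random.default_rng(s0)
    shifted = set(rng.choice(headroom, size=50, replace=False))
    shift = pd.Series(-0.05, index=base.gene_params.index)
    shift[list(shifted)] = -0.05 - 0.20
    truth = syn.make_truth(seqs, ann, tes, seed=s0 + 1, stages=("A", "B"),
                           erosion=(1.0, 1.0), te_mode=False,
                           stage_gene_shift={"B": shift})
    gbm_a = gene_body_methylation(syn.generate_methylome(truth, "A", 30, seed=s0 + 2), ann)
    gbm_b = gene_body_methylation(syn.generate_methylome(truth, "B", 30, seed=s0 + 3), ann)
    calls = detect_gbm_changes(gbm_a, gbm_b)
    in_plant = calls.index.isin(shifted)
    return {
        "sensitivity": float(calls.loc[in_plant, "call"].eq("hypomethylated").mean()),
        "false_call_rate": float((calls.loc[~in_plant, "call"] != "stable").mean()),
        "global_mean_difference": float(calls["global_mean_difference"].iloc[0]),
        "n_planted": int(in_plant.sum()),
        "n_stable": int((~in_plant).sum()),
    }


def umr_recovery(seed: int = 1) -> dict:
    """Planted unmethylated promoters on a hypermethylated validation genome."""
    s0 = _sub(seed, 60)
    seqs, ann, tes, _ = syn.generate_genome(
        n_contigs=2, contig_length=700_000, n_genes=220, n_tes=80,
        seed=s0, gene_length=(1500, 3000), min_gap=1800)
    truth = syn.make_truth(seqs, ann, tes, seed=s0 + 1, background_level=0.78,
                           gbm_range=(0.65, 0.90), expression_link=False,
                           cv_link=False, n_umrs=200)
    meth = syn.generate_methylome(truth, "gastrula", mean_depth=30, seed=s0 + 2)
    umrs = call_umrs(meth)
    recovered = sum(
        any(u.contig == r.contig and u.start < r.end and u.end > r.start for u in umrs)
        for r in truth.umrs.itertuples())
    # a run of 3 low CpGs must never be called
    short_run = MethylomeTable("short_run", pd.DataFrame(
        [("c", p, "+", "CG", m, 20) for p, m in
         [(100, 18), (120, 19), (140, 0), (160, 1), (180, 0), (200, 18), (220, 17)]],
        columns=METH_COLUMNS))
    short_called = len(call_umrs(short_run)) > 0
    min_ncpg = min((u.n_cpgs for u in umrs), default=4)
    # strict < 5 kb promoter-summary boundary: a 5000 bp UMR is excluded
    genes = pd.DataFrame([("gX", "c", "+", 20_000, 22_000)],
                         columns=["gene_id", "contig", "strand", "start", "end"]).set_index("gene_id")
    tiny = GenomeAnnotation(genes, {"gX": [(20_000, 22_000)]}, {"c": 50_000})
    boundary = promoter_umr_summary(
        [UMR("c", 1000, 6000, 50, 0.01), UMR("c", 19_000, 20_500, 12, 0.01)], tiny)
    size_filter_strict = boundary["n_excluded_by_size"] == 1 and boundary["n_umrs"] == 1
    return {
        "recovered_fraction": recovered / len(truth.umrs),
        "n_planted": len(truth.umrs),
        "n_called": len(umrs),
        "short_run_never_called": (not short_called) and min_ncpg >= 4,
        "size_filter_strict": bool(size_filter_strict),
    }


def statistical_calibration(seed: int = 1, n_ttest_sims: int = 1000,
                            n_tede_sims: int = 5) -> dict:
    """Type-I error of the two tests and recovery of a planted 4.2% depletion."""
    s0 = _sub(seed, 70)
    # t-test calibration: replicate arms drawn from the same condition
    seqs, ann, tes, _ = syn.generate_genome(
        n_contigs=1, contig_length=60_000, n_genes=15, n_tes=5,
        seed=s0, gene_length=(800, 1600), min_gap=1200)
    truth = syn.make_truth(seqs, ann, tes, seed=s0 + 1)
    reject = 0
    for i in range(n_ttest_sims):
        reps = [syn.generate_methylome(truth, "gastrula", 3.0, seed=s0 % 10**6 + 10 + 6 * i + j,
                                       include_spikes=False, include_non_cg=False)
                for j in range(6)]
        if compare_depletion(reps[:3], reps[3:])["p"] <= 0.05:
            reject += 1
    ttest_type1 = reject / n_ttest_sims

    # TE differential expression under the null
    rng = np.random.default_rng(s0 + 5)
    n_te = 1000
    null_ps = []
    for _ in range(n_tede_sims):
        mu = rng.lognormal(4, 1, n_te)
        counts = pd.DataFrame({f"s{k}": rng.poisson(mu) for k in range(4)},
                              index=[f"TE{i}" for i in range(n_te)])
        res = te_differential_expression(
            counts, pd.Series({"s0": "c", "s1": "c", "s2": "z", "s3": "z"}),
            alpha=0.05, min_abs_l2fc=0.0)
        null_ps.append(res["p"].to_numpy())
    tede_type1 = float(np.mean(np.concatenate(null_ps) <= 0.05))

    # planted global depletion
    s1 = _sub(seed, 80)
    seqs2, ann2, tes2, _ = syn.generate_genome(
        n_contigs=2, contig_length=1_000_000, n_genes=1000, n_tes=400,
        seed=s1, gene_length=(800, 1600), min_gap=200)
    truth2 = syn.make_truth(seqs2, ann2, tes2, seed=s1 + 1)
    ctrl = [syn.generate_methylome(truth2, "larva", 8.0, seed=s1 + 10 + i,
                                   include_spikes=False, include_non_cg=False)
            for i in range(3)]
    trt = [syn.apply_global_depletion(
        syn.generate_methylome(truth2, "larva", 8.0, seed=s1 + 20 + i,
                               include_spikes=False, include_non_cg=False),
        truth2.depletion_fraction, seed=s1 + 30 + i) for i in range(3)]
    res = compare_depletion(ctrl, trt)
    return {
        "ttest_type1": ttest_type1,
        "tede_type1": tede_type1,
        "depletion_relative_pct": res["relative_depletion"] * 100.0,
        "depletion_error_pp": abs(res["relative_depletion"] * 100.0
                                  - truth2.depletion_fraction * 100.0),
        "depletion_p": res["p"],
        "n_ttest_sims": n_ttest_sims,
        "n_tede_tests": n_te * n_tede_sims,
    }
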