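"""Transposable-element methylation and unmethylated-region segmentation.

TEs are filtered by length (> 400 bp), split into genic and intergenic,
scored for methylation (>= 20% defined as methylated) and stratified against
intron structure; a simplified deterministic differential-expression test
covers TE reactivation analyses.  UMRs are maximal runs of lowly methylated
consecutive CpGs, summarized against promoters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeAnnotation, MethylomeTable, RegionSet


def filter_and_classify_tes(
    tes: RegionSet,
    annotation: GenomeAnnotation,
    methylome: MethylomeTable,
    min_len: int = 400,
    meth_threshold: float = 0.2,
    min_mean_cov: float = 4.0,
    min_cpgs: int = 5,
) -> pd.DataFrame:
    """Length-filter, locate and score TEs for methylation.

    Keeps TEs strictly longer than ``min_len``; a TE is genic when it
    overlaps any gene span by >= 1 bp.  Methylation is the count-weighted
    mCG over the TE's CpGs, subject to the same per-feature coverage filters
    as genes; TEs failing them keep a missing fraction and ``undefined``
    status.  Family comes from the ``label`` suffix after ``#`` when present.
    """
    df = tes.intervals.copy()
    df["length"] = df["end"] - df["start"]
    df = df[df["length"] > min_len].reset_index(drop=True)
    genes = annotation.genes
    cg = methylome.records[methylome.records["context"] == "CG"]
    by_contig = {c: sub.reset_index(drop=True) for c, sub in cg.groupby("contig")}
    loc, frac, status, containing = [], [], [], []
    for r in df.itertuples(index=False):
        sub = genes[(genes["contig"] == r.contig) & (genes["start"] < r.end) & (genes["end"] > r.start)]
        loc.append("genic" if len(sub) else "intergenic")
        containing.append(sub.index[0] if len(sub) else "")
        msub = by_contig.get(r.contig)
        n_meth = n_total = n_cpg = 0
        if msub is not None:
            pos0 = msub["pos"].to_numpy() - 1
            lo, hi = np.searchsorted(pos0, (r.start, r.end))
            n_cpg = hi - lo
            n_meth = int(msub["n_meth"].to_numpy()[lo:hi].sum())
            n_total = int(msub["n_total"].to_numpy()[lo:hi].sum())
        if n_cpg < min_cpgs or (n_cpg and n_total / n_cpg < min_mean_cov) or n_total == 0:
            frac.append(np.nan)
            status.append("undefined")
        else:
            f = n_meth / n_total
            frac.append(f)
            status.append("methylated" if f >= meth_threshold else "unmethylated")
    df["family"] = df["label"].str.split("#").str[-1].where(df["label"].str.contains("#"), "unknown")
    df["location"] = loc
    df["containing_gene"] = containing
    df["methylation"] = frac
    df["status"] = status
    return df


def gbm_by_intron_te_strata(
    gbm: pd.DataFrame,
    annotation: GenomeAnnotation,
    tes: RegionSet,
    min_len: int = 400,
    max_intron_bin: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GbM stratified by intron count and intronic-TE presence.

    Each passing gene is assigned (intron-count bin, number of introns
    containing a retained TE).  Returns the per-gene stratum table and a
    per-intron-bin comparison of with-TE vs without-TE genes (two-sided
    Wilcoxon rank-sum); empty strata are skipped.
    """
    te_df = tes.intervals.copy()
    te_df = te_df[(te_df["end"] - te_df["start"]) > min_len]
    by_contig = {c: sub.sort_values("start") for c, sub in te_df.groupby("contig")}
    rows = []
    passed = gbm[gbm["passed"]]
    for gid in passed.index:
        g = annotation.genes.loc[gid]
        introns = annotation.introns(gid)
        sub = by_contig.get(g["contig"])
        n_te_introns = 0
        if sub is not None and introns:
            ts = sub["start"].to_numpy()
            te_ = sub["end"].to_numpy()
            for s, e in introns:
                if ((ts < e) & (te_ > s)).any():
                    n_te_introns += 1
        rows.append((gid, len(introns), min(len(introns), max_intron_bin), n_te_introns,
                     passed.loc[gid, "gbm"]))
    strata = pd.DataFrame(
        rows, columns=["gene_id", "n_introns", "intron_bin", "n_te_introns", "gbm"]
    ).set_index("gene_id")
    comp_rows = []
    for ib, sub in strata[strata["n_introns"] > 0].groupby("intron_bin"):
        with_te = sub[sub["n_te_introns"] > 0]["gbm"]
        without = sub[sub["n_te_introns"] == 0]["gbm"]
        if len(with_te) == 0 or len(without) == 0:
            continue
        u, p = stats.mannwhitneyu(with_te, without, alternative="two-sided")
        comp_rows.append((ib, len(with_te), len(without),
                          float(with_te.median()), float(without.median()), float(u), float(p)))
    comparison = pd.DataFrame(
        comp_rows,
        columns=["intron_bin", "n_with_te", "n_without_te", "median_with_te",
                 "median_without_te", "statistic", "p"],
    )
    return strata, comparison


def te_differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    te_table: pd.DataFrame | None = None,
    alpha: float = 0.01,
    min_abs_l2fc: float = 2.0,
    prior_df: float = 20.0,
    trend_bins: int = 20,
) -> pd.DataFrame:
    """Simplified deterministic TE differential expression.

    Median-of-ratios library normalization, then a two-sided moderated t on
    log2(normalized + 1): per-TE pooled variances are shrunk toward an
    abundance-trended prior (the mean pooled variance in the TE's
    average-abundance quantile bin) with ``prior_df`` prior degrees of
    freedom, which keeps the test calibrated and powered at the tiny
    replicate numbers typical of TE experiments.  Benjamini-Hochberg
    adjustment; a TE is called when padj <= ``alpha`` and |log2 fold change|
    >= ``min_abs_l2fc``.  All-zero rows are dropped (their count is in the
    ``n_all_zero`` attribute).  When a classified TE table is supplied (from
    :func:`filter_and_classify_tes`), calls are cross-tabulated by location
    and family in the ``location_crosstab`` / ``family_crosstab`` attributes.
    """
    groups = pd.Series(groups)
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    g1 = list(groups[groups == labels[0]].index)
    g2 = list(groups[groups == labels[1]].index)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 replicates per group")
    mat = counts[g1 + g2]
    nonzero = mat.sum(axis=1) > 0
    n_all_zero = int((~nonzero).sum())
    mat = mat[nonzero].astype(float)

    # median-of-ratios size factors (rows with any zero excluded from the reference)
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat.replace(0, np.nan)).mean(axis=1)
        ref_ok = np.isfinite(log_geo)
        ratios = np.log(mat.loc[ref_ok]) - log_geo[ref_ok].to_numpy()[:, None]
    size = np.exp(np.median(ratios, axis=0)) if ref_ok.any() else np.ones(mat.shape[1])
    norm = mat / size
    log_norm = np.log2(norm + 1)

    x1 = log_norm[g1].to_numpy()
    x2 = log_norm[g2].to_numpy()
    n1, n2 = len(g1), len(g2)
    l2fc = np.log2((norm[g2].mean(axis=1) + 1) / (norm[g1].mean(axis=1) + 1))
    resid_df = n1 + n2 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / resid_df
    abundance = log_norm.mean(axis=1).to_numpy()
    nbins = min(trend_bins, max(1, len(s2) // 20))
    bins = pd.qcut(abundance, nbins, labels=False, duplicates="drop") if nbins > 1 else np.zeros(len(s2))
    prior_var = np.empty(len(s2))
    for b in np.unique(bins):
        mask = bins == b
        prior_var[mask] = s2[mask].mean()
    s2_mod = (prior_df * prior_var + resid_df * s2) / (prior_df + resid_df)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (x2.mean(axis=1) - x1.mean(axis=1)) / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), prior_df + resid_df)
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    res = pd.DataFrame({
        "log2fc": l2fc, "t": t, "p": p, "padj": padj,
    }, index=mat.index)
    res["call"] = np.select(
        [(res["padj"] <= alpha) & (res["log2fc"] >= min_abs_l2fc),
         (res["padj"] <= alpha) & (res["log2fc"] <= -min_abs_l2fc)],
        ["up", "down"], default="ns",
    )
    res.attrs["n_all_zero"] = n_all_zero
    if te_table is not None:
        joined = res.join(te_table.set_index("label")[["location", "family"]], how="left")
        called = joined[joined["call"] != "ns"]
        res.attrs["location_crosstab"] = pd.crosstab(called["call"], called["location"])
        res.attrs["family_crosstab"] = pd.crosstab(called["call"], called["family"])
    return res


@dataclass
class UMR:
    contig: str
    start: int   # 0-based half-open, first to last CpG of the run
    end: int
    n_cpgs: int
    mean_methylation: float

    @property
    def size(self) -> int:
        return self.end - self.start


def call_umrs(
    methylome: MethylomeTable,
    meth_cutoff: float = 0.5,
    ncpg_cutoff: int = 4,
    min_cov: int = 4,
) -> list[UMR]:
    """Segment unmethylated regions as maximal low-methylation CpG runs.

    Over CpGs covered >= ``min_cov``, a UMR is a maximal run of consecutive
    CpGs each with methylation fraction < ``meth_cutoff``, kept when the run
    has >= ``ncpg_cutoff`` CpGs.  Region bounds span the first to last CpG
    of the run.  Returned UMRs are disjoint and sorted; zero is a valid
    result.
    """
    cg = methylome.records[
        (methylome.records["context"] == "CG") & (methylome.records["n_total"] >= min_cov)
    ]
    out: list[UMR] = []
    for contig, sub in cg.groupby("contig", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy() - 1
        frac = sub["n_meth"].to_numpy() / sub["n_total"].to_numpy()
        low = frac < meth_cutoff
        # run boundaries of the boolean vector
        edges = np.flatnonzero(np.diff(np.concatenate([[0], low.view(np.int8), [0]])))
        for s_i, e_i in zip(edges[::2], edges[1::2]):
            if e_i - s_i < ncpg_cutoff:
                continue
            out.append(UMR(
                contig=contig, start=int(pos[s_i]), end=int(pos[e_i - 1]) + 2,
                n_cpgs=int(e_i - s_i), mean_methylation=float(frac[s_i:e_i].mean()),
            ))
    return out


def promoter_umr_summary(
    umrs: list[UMR],
    annotation: GenomeAnnotation,
    max_size: int = 5000,
    promoter_def: tuple[int, int] = (2000, 200),
) -> dict:
    """Promoter overlap of size-filtered UMRs.

    UMRs of size strictly below ``max_size`` are intersected with
    strand-aware promoters (default 2 kb upstream / 200 bp downstream of
    each TSS).  Returns the promoter-overlap fraction and the size
    distributions of promoter vs non-promoter UMRs.
    """
    prom = annotation.promoters(*promoter_def)
    by_contig = {c: sub for c, sub in prom.groupby("contig")}
    kept = [u for u in umrs if u.size < max_size]
    flags = []
    for u in kept:
        sub = by_contig.get(u.contig)
        hit = bool(sub is not None and ((sub["start"] < u.end) & (sub["end"] > u.start)).any())
        flags.append(hit)
    sizes = np.array([u.size for u in kept])
    flags_arr = np.array(flags, dtype=bool) if flags else np.array([], dtype=bool)
    return {
        "n_umrs": len(kept),
        "n_excluded_by_size": len(umrs) - len(kept),
        "promoter_fraction": float(flags_arr.mean()) if len(kept) else np.nan,
        "promoter_sizes": sizes[flags_arr],
        "other_sizes": sizes[~flags_arr],
        "promoter_flags": flags_arr,
    }


def compare_umr_sizes(summary1: dict, summary2: dict) -> dict:
    """Two-sided t-test on promoter-UMR sizes between two datasets."""
    s1, s2 = summary1["promoter_sizes"], summary2["promoter_sizes"]
    if len(s1) < 2 or len(s2) < 2:
        return {"tested": False, "t": np.nan, "p": np.nan}
    t, p = stats.ttest_ind(s1, s2, equal_var=False)
    return {"tested": True, "t": float(t), "p": float(p),
            "median1": float(np.median(s1)), "median2": float(np.median(s2))}
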