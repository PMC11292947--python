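"""Interspecies one-to-one orthologue GbM comparison.

Orthology is consumed as a two-column table (never inferred here).  Pairs in
which both genes pass the GbM coverage filters are classified by the 20%
methylation threshold into methylated-both / unmethylated-both /
hypermethylated-in-either-species, and the classes are related to
between-species differences in expression level and stability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .gbm import expression_summary, quantile_normalize

CLASSES = ("methylated_both", "unmethylated_both", "hyper_sp1", "hyper_sp2")


def classify_orthologue_pairs(
    gbm1: pd.DataFrame,
    gbm2: pd.DataFrame,
    pairs: pd.DataFrame,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Four-way GbM classification of orthologue pairs.

    Both >= threshold -> methylated_both; both < threshold ->
    unmethylated_both; one-sided -> hyper_sp1 / hyper_sp2.  Pairs with a
    fail-flagged gene in either species are excluded (their count is in the
    ``n_excluded`` DataFrame attribute).  Swapping the species maps
    hyper_sp1 <-> hyper_sp2 and fixes the symmetric classes.
    """
    p1 = gbm1[gbm1["passed"]]["gbm"]
    p2 = gbm2[gbm2["passed"]]["gbm"]
    ok = pairs["gene1"].isin(p1.index) & pairs["gene2"].isin(p2.index)
    kept = pairs[ok].copy()
    kept["gbm1"] = p1.loc[kept["gene1"]].to_numpy()
    kept["gbm2"] = p2.loc[kept["gene2"]].to_numpy()
    m1 = kept["gbm1"] >= threshold
    m2 = kept["gbm2"] >= threshold
    cls = np.select(
        [m1 & m2, ~m1 & ~m2, m1 & ~m2],
        ["methylated_both", "unmethylated_both", "hyper_sp1"],
        default="hyper_sp2",
    )
    kept["class"] = cls
    kept = kept.reset_index(drop=True)
    kept.attrs["n_excluded"] = int((~ok).sum())
    kept.attrs["class_fractions"] = kept["class"].value_counts(normalize=True).to_dict()
    return kept


def interspecies_trajectories(
    gbm1_by_stage: dict[str, pd.DataFrame],
    gbm2_by_stage: dict[str, pd.DataFrame],
    expr1: pd.DataFrame,
    expr2: pd.DataFrame,
    pairs: pd.DataFrame,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-stage cross-species rank correlations of GbM and of expression.

    For each stage shared by both species, Spearman correlation across
    orthologue pairs of (i) GbM and (ii) log expression.  Stages with fewer
    than ``min_pairs`` classified pairs are skipped (flagged with NaN).
    """
    shared_stages = [s for s in gbm1_by_stage if s in gbm2_by_stage]
    if len(shared_stages) < 2:
        raise ValueError("need at least 2 shared stages")
    rows = []
    for stage in shared_stages:
        p1 = gbm1_by_stage[stage]
        p2 = gbm2_by_stage[stage]
        ok1 = p1[p1["passed"]]["gbm"]
        ok2 = p2[p2["passed"]]["gbm"]
        sel = pairs[pairs["gene1"].isin(ok1.index) & pairs["gene2"].isin(ok2.index)]
        if len(sel) < min_pairs:
            rows.append((stage, np.nan, np.nan, len(sel), True))
            continue
        g1 = ok1.loc[sel["gene1"]].to_numpy()
        g2 = ok2.loc[sel["gene2"]].to_numpy()
        r_gbm = stats.spearmanr(g1, g2).statistic
        e1 = np.log1p(expr1.loc[sel["gene1"], stage].to_numpy())
        e2 = np.log1p(expr2.loc[sel["gene2"], stage].to_numpy())
        r_expr = stats.spearmanr(e1, e2).statistic
        rows.append((stage, float(r_gbm), float(r_expr), len(sel), False))
    return pd.DataFrame(rows, columns=["stage", "r_gbm", "r_expression", "n_pairs", "skipped"]
                        ).set_index("stage")


def class_vs_expression(
    comparison: pd.DataFrame,
    expr1: pd.DataFrame,
    expr2: pd.DataFrame,
    normalize: bool = True,
    min_class_size: int = 3,
) -> pd.DataFrame:
    """Per-class between-species differences in expression and stability.

    For every classified pair the species-1-minus-species-2 difference of
    log2 mean expression and of expression CV is computed (within-species
    quantile normalization of the stage columns by default).  Each
    hypermethylated class is contrasted against the symmetric-class pool
    with a two-sided t-test; classes smaller than ``min_class_size`` have
    their statistics skipped (NaN).
    """
    e1 = quantile_normalize(expr1) if normalize else expr1
    e2 = quantile_normalize(expr2) if normalize else expr2
    s1 = expression_summary(e1)
    s2 = expression_summary(e2)
    df = comparison.copy()
    df["d_log_expr"] = (
        np.log2(s1.loc[df["gene1"], "mean_tpm"].to_numpy() + 1)
        - np.log2(s2.loc[df["gene2"], "mean_tpm"].to_numpy() + 1)
    )
    df["d_cv"] = s1.loc[df["gene1"], "cv"].to_numpy() - s2.loc[df["gene2"], "cv"].to_numpy()
    symmetric = df[df["class"].isin(["methylated_both", "unmethylated_both"])]
    rows = []
    for cls, sub in df.groupby("class"):
        row = {
            "class": cls, "n": len(sub),
            "mean_d_log_expr": float(sub["d_log_expr"].mean()),
            "mean_d_cv": float(np.nanmean(sub["d_cv"])),
            "t_expr": np.nan, "p_expr": np.nan, "t_cv": np.nan, "p_cv": np.nan,
        }
        if cls in ("hyper_sp1", "hyper_sp2") and len(sub) >= min_class_size and len(symmetric) >= min_class_size:
            t, p = stats.ttest_ind(sub["d_log_expr"], symmetric["d_log_expr"], equal_var=False)
            row.update(t_expr=float(t), p_expr=float(p))
            t, p = stats.ttest_ind(sub["d_cv"].dropna(), symmetric["d_cv"].dropna(), equal_var=False)
            row.update(t_cv=float(t), p_cv=float(p))
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
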