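"""Per-gene body methylation and its coupling to transcription.

Gene body methylation (GbM) is the count-weighted fraction of methylated CpG
calls across a gene's full transcript span (introns included).  Genes are
kept only when they carry at least five covered CpGs with a mean coverage of
at least four; the passing genes are then related to expression level and to
transcriptional stability (coefficient of variation across stages) through
decile ranking and rank correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeAnnotation, MethylomeTable

NON_EXPRESSED = "non_expressed"


def gene_body_methylation(
    methylome: MethylomeTable,
    annotation: GenomeAnnotation,
    min_mean_cov: float = 4.0,
    min_cpgs: int = 5,
    feature: str = "body",
) -> pd.DataFrame:
    """Per-gene GbM table with pass/fail filter flags.

    ``feature`` selects the CpGs used: the whole transcript span (default),
    or ``exon`` / ``intron`` for the per-feature secondary summaries.
    Returns a DataFrame indexed by gene_id with columns ``gbm, n_cpgs,
    mean_cov, passed, fail_reason``; fail reasons are ``no_cpg``,
    ``min_cpgs`` or ``min_mean_cov``.
    """
    if feature not in ("body", "exon", "intron"):
        raise ValueError(f"unknown feature {feature!r}")
    cg = methylome.records[methylome.records["context"] == "CG"]
    by_contig = {c: sub.reset_index(drop=True) for c, sub in cg.groupby("contig")}
    rows = []
    for gid, g in annotation.genes.iterrows():
        sub = by_contig.get(g["contig"])
        if feature == "body":
            intervals = [(int(g["start"]), int(g["end"]))]
        elif feature == "exon":
            intervals = annotation.exons[gid]
        else:
            intervals = annotation.introns(gid)
        n_meth = n_total = n_cpg = 0
        if sub is not None and intervals:
            pos0 = sub["pos"].to_numpy() - 1
            for s, e in intervals:
                lo, hi = np.searchsorted(pos0, (s, e))
                if hi > lo:
                    n_cpg += hi - lo
                    n_meth += int(sub["n_meth"].to_numpy()[lo:hi].sum())
                    n_total += int(sub["n_total"].to_numpy()[lo:hi].sum())
        mean_cov = n_total / n_cpg if n_cpg else 0.0
        if n_cpg == 0:
            rows.append((gid, np.nan, 0, 0.0, False, "no_cpg"))
        elif n_cpg < min_cpgs:
            rows.append((gid, np.nan, n_cpg, mean_cov, False, "min_cpgs"))
        elif mean_cov < min_mean_cov:
            rows.append((gid, np.nan, n_cpg, mean_cov, False, "min_mean_cov"))
        else:
            rows.append((gid, n_meth / n_total, n_cpg, mean_cov, True, ""))
    return pd.DataFrame(
        rows, columns=["gene_id", "gbm", "n_cpgs", "mean_cov", "passed", "fail_reason"]
    ).set_index("gene_id")


def classify_methylation_status(gbm: pd.DataFrame, threshold: float = 0.2,
                                strict: bool = False) -> pd.Series:
    """Binary methylated/unmethylated status for passing genes.

    Default rule: methylated iff GbM >= threshold (the 20% convention).
    ``strict`` switches to a strictly-greater comparison (the 10% rule used
    for treatment analyses).
    """
    passed = gbm[gbm["passed"]]
    if strict:
        meth = passed["gbm"] > threshold
    else:
        meth = passed["gbm"] >= threshold
    return meth.map({True: "methylated", False: "unmethylated"})


def expression_summary(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean TPM and coefficient of variation across stages.

    CV = sd/mean on the TPM scale; undefined (NaN) for all-zero genes.
    """
    mean = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame({"mean_tpm": mean, "cv": cv}, index=expression.index)


def quantile_normalize(expression: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the stage columns (rank-based, mean reference)."""
    ranks = expression.rank(method="first").astype(int) - 1
    ref = np.sort(expression.to_numpy(), axis=0).mean(axis=1)
    return pd.DataFrame(ref[ranks.to_numpy()], index=expression.index,
                        columns=expression.columns)


def rank_deciles(values: pd.Series, n: int = 10, min_value: float | None = None) -> pd.Series:
    """Near-equal-size quantile groups (0..n-1) with a deterministic tie-break.

    Values below ``min_value`` (when given) land in the dedicated
    ``non_expressed`` class before ranking.  Ranks use the value order with
    a stable index tie-break, so group sizes differ by at most one.
    """
    values = values.dropna()
    out = pd.Series(pd.NA, index=values.index, dtype="object")
    if min_value is not None:
        excluded = values < min_value
        out[excluded] = NON_EXPRESSED
        ranked = values[~excluded]
    else:
        ranked = values
    if ranked.nunique() < n:
        raise ValueError(f"fewer than {n} distinct values; use a smaller n")
    order = ranked.sort_values(kind="mergesort").index  # stable: ties by input order
    m = len(order)
    groups = np.floor(np.arange(m) * n / m).astype(int)
    out.loc[order] = groups
    return out


def gbm_by_decile(gbm: pd.DataFrame, deciles: pd.Series) -> pd.DataFrame:
    """Per-decile GbM distribution summary (median, quartiles, n, genes)."""
    passed = gbm[gbm["passed"]]
    shared = passed.index.intersection(deciles.dropna().index)
    if len(shared) == 0:
        raise ValueError("no genes shared between GbM table and decile assignment")
    df = pd.DataFrame({"gbm": passed.loc[shared, "gbm"], "decile": deciles.loc[shared]})
    rows = []
    for dec, sub in df.groupby("decile", sort=False):
        q1, med, q3 = sub["gbm"].quantile([0.25, 0.5, 0.75])
        rows.append((dec, len(sub), q1, med, q3, list(sub.index)))
    out = pd.DataFrame(rows, columns=["decile", "n", "q1", "median", "q3", "genes"])
    numeric = out[out["decile"] != NON_EXPRESSED].copy()
    numeric["__k"] = numeric["decile"].astype(int)
    numeric = numeric.sort_values("__k").drop(columns="__k")
    non = out[out["decile"] == NON_EXPRESSED]
    return pd.concat([numeric, non], ignore_index=True)


def gbm_expression_correlation(
    gbm_by_stage: dict[str, pd.DataFrame],
    expression: pd.DataFrame,
    method: str = "spearman",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-stage correlation between GbM and (log) expression.

    Rank correlation is the headline statistic (robust to the TPM tail);
    Pearson on log(TPM + pseudocount) is available via ``method``.  Stages
    are taken in the order of ``gbm_by_stage``; requires >= 10 paired genes
    per stage.
    """
    rows = []
    for stage, gbm in gbm_by_stage.items():
        if stage not in expression.columns:
            raise KeyError(f"stage {stage!r} absent from expression matrix")
        passed = gbm[gbm["passed"]]
        shared = passed.index.intersection(expression.index)
        if len(shared) < 10:
            raise ValueError(f"stage {stage!r}: fewer than 10 paired genes")
        x = passed.loc[shared, "gbm"]
        y = np.log(expression.loc[shared, stage] + pseudocount)
        if method == "spearman":
            r, p = stats.spearmanr(x, y)
        elif method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((stage, float(r), float(p), len(shared)))
    return pd.DataFrame(rows, columns=["stage", "r", "p", "n"]).set_index("stage")
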