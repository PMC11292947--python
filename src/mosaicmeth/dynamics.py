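"""Between-stage methylome dynamics.

The twofold GbM-change rule, a deterministic differentially-methylated-region
(DMR) caller, genomic annotation of regions, treatment-depletion comparison
and aging trajectories from shallow-coverage samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import global_mcg
from .io_formats import GenomeAnnotation, MethylomeTable, RegionSet


def detect_gbm_changes(
    gbm_a: pd.DataFrame,
    gbm_b: pd.DataFrame,
    fold: float = 2.0,
    rule: str = "deviation",
    abs_threshold: float = 0.1,
) -> pd.DataFrame:
    """Call genes whose GbM change deviates from the global trend.

    For genes passing filters in both stages, the mean difference d_bar
    (B - A, over all shared genes) captures the global methylation drift; a
    gene is called when its deviation from it exceeds ``fold`` times |d_bar|
    (``rule='deviation'``: |d_g - d_bar| > fold*|d_bar|) — the alternative
    ``rule='abs2x'`` compares |d_g| > fold*|d_bar|.  When d_bar is exactly 0
    the call falls back to an absolute-difference threshold, flagged in the
    output.  Direction comes from the sign of (d_g - d_bar).
    """
    if rule not in ("deviation", "abs2x"):
        raise ValueError(f"unknown rule {rule!r}")
    a = gbm_a[gbm_a["passed"]]["gbm"]
    b = gbm_b[gbm_b["passed"]]["gbm"]
    shared = a.index.intersection(b.index)
    diff = (b.loc[shared] - a.loc[shared]).astype(float)
    d_bar = float(diff.mean())
    fallback = d_bar == 0.0
    dev = diff - d_bar
    if fallback:
        called = dev.abs() > abs_threshold
    elif rule == "deviation":
        called = dev.abs() > fold * abs(d_bar)
    else:
        called = diff.abs() > fold * abs(d_bar)
    call = pd.Series("stable", index=shared, dtype="object")
    call[called & (dev > 0)] = "hypermethylated"
    call[called & (dev < 0)] = "hypomethylated"
    return pd.DataFrame({
        "gbm_a": a.loc[shared], "gbm_b": b.loc[shared], "difference": diff,
        "global_mean_difference": d_bar, "call": call,
        "absolute_fallback": fallback,
    })


@dataclass
class DMR:
    contig: str
    start: int       # 0-based half-open, spanning first to last seed CpG
    end: int
    n_cpgs: int
    mean_difference: float   # region-mean raw difference (B - A)
    direction: str           # hyper/hypo in sample B relative to A
    category: str = ""
    contains_te: bool = False


def call_dmrs(
    methylome_a: MethylomeTable,
    methylome_b: MethylomeTable,
    delta: float = 0.2,
    min_cg: int = 5,
    merge_dist: int = 100,
    min_cov: int = 4,
    smooth_window: int = 3,
) -> list[DMR]:
    """Deterministic two-sample DMR caller.

    At CpGs covered >= ``min_cov`` in both samples, the per-CpG methylation
    difference (B - A) is smoothed with a centred running mean over
    ``smooth_window`` CpGs; seed CpGs with |smoothed difference| > ``delta``
    are merged when consecutive, same-direction and within ``merge_dist``
    bases; merged runs with >= ``min_cg`` seeds and region mean coverage >=
    ``min_cov`` are reported with their raw region-mean difference.  Zero
    DMRs is a valid result; calls on (A, B) equal direction-flipped calls on
    (B, A).
    """
    a = methylome_a.records[methylome_a.records["context"] == "CG"]
    b = methylome_b.records[methylome_b.records["context"] == "CG"]
    merged = a.merge(b, on=["contig", "pos"], suffixes=("_a", "_b"))
    merged = merged[(merged["n_total_a"] >= min_cov) & (merged["n_total_b"] >= min_cov)]
    out: list[DMR] = []
    half = smooth_window // 2
    for contig, sub in merged.groupby("contig", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy() - 1
        fa = sub["n_meth_a"].to_numpy() / sub["n_total_a"].to_numpy()
        fb = sub["n_meth_b"].to_numpy() / sub["n_total_b"].to_numpy()
        diff = fb - fa
        if len(diff) == 0:
            continue
        kernel = np.ones(smooth_window) / smooth_window
        if len(diff) >= smooth_window:
            smooth = np.convolve(diff, kernel, mode="same")
            # edges: shrink to available window
            for i in range(half):
                smooth[i] = diff[: i + half + 1].mean()
                smooth[-(i + 1)] = diff[-(i + half + 1):].mean()
        else:
            smooth = np.full(len(diff), diff.mean())
        seed = np.abs(smooth) > delta
        sign = np.sign(smooth)
        idx = np.flatnonzero(seed)
        if len(idx) == 0:
            continue
        runs: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            prev = runs[-1][-1]
            if pos[i] - pos[prev] <= merge_dist and sign[i] == sign[prev]:
                runs[-1].append(i)
            else:
                runs.append([i])
        cov_a = sub["n_total_a"].to_numpy()
        cov_b = sub["n_total_b"].to_numpy()
        for run in runs:
            if len(run) < min_cg:
                continue
            i0, i1 = run[0], run[-1]
            mean_cov = 0.5 * (cov_a[i0:i1 + 1].mean() + cov_b[i0:i1 + 1].mean())
            if mean_cov < min_cov:
                continue
            raw = float(diff[i0:i1 + 1].mean())
            out.append(DMR(
                contig=contig, start=int(pos[i0]), end=int(pos[i1]) + 2,
                n_cpgs=len(run), mean_difference=raw,
                direction="hyper" if smooth[run[0]] > 0 else "hypo",
            ))
    return out


def annotate_regions(
    regions: list[DMR] | pd.DataFrame,
    annotation: GenomeAnnotation,
    atac: RegionSet | None = None,
    tes: RegionSet | None = None,
    promoter_def: tuple[int, int] = (1000, 200),
) -> pd.DataFrame:
    """Assign each region one genomic category (plus a TE-overlap flag).

    Precedence: promoter > exon > intron > distal-regulatory (ATAC peak
    outside promoters) > intergenic.  Promoters are strand-aware windows of
    ``promoter_def`` = (upstream, downstream) bases around each TSS; the
    (1000, 200) default is the distal-element convention.  Regions on a
    contig absent from the annotation get ``unplaced`` with a warning.
    """
    if isinstance(regions, list):
        df = pd.DataFrame([{
            "contig": r.contig, "start": r.start, "end": r.end, "n_cpgs": r.n_cpgs,
            "mean_difference": r.mean_difference, "direction": r.direction,
        } for r in regions])
    else:
        df = regions.copy()
    if df.empty:
        df["category"] = pd.Series(dtype="object")
        df["contains_te"] = pd.Series(dtype="bool")
        return df

    known = set(annotation.contig_lengths) or set(annotation.genes["contig"])

    def _tree(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for r in intervals.itertuples(index=False):
            trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end)
        return trees

    prom = _tree(annotation.promoters(*promoter_def))
    exon_rows, intron_rows = [], []
    for gid, g in annotation.genes.iterrows():
        for s, e in annotation.exons[gid]:
            exon_rows.append((g["contig"], s, e))
        for s, e in annotation.introns(gid):
            intron_rows.append((g["contig"], s, e))
    exon_t = _tree(pd.DataFrame(exon_rows, columns=["contig", "start", "end"])) if exon_rows else {}
    intron_t = _tree(pd.DataFrame(intron_rows, columns=["contig", "start", "end"])) if intron_rows else {}
    atac_t = _tree(atac.intervals) if atac is not None else {}
    te_t = _tree(tes.intervals) if tes is not None else {}

    cats, te_flags = [], []
    for r in df.itertuples(index=False):
        if r.contig not in known:
            warnings.warn(f"region on unknown contig {r.contig!r}")
            cats.append("unplaced")
            te_flags.append(False)
            continue
        s, e = int(r.start), int(r.end)

        def _hits(trees):
            return r.contig in trees and bool(trees[r.contig].overlap(s, e))

        if _hits(prom):
            cats.append("promoter")
        elif _hits(exon_t):
            cats.append("exon")
        elif _hits(intron_t):
            cats.append("intron")
        elif _hits(atac_t):
            cats.append("distal_regulatory")
        else:
            cats.append("intergenic")
        te_flags.append(_hits(te_t))
    df["category"] = cats
    df["contains_te"] = te_flags
    return df


def compare_depletion(
    control_replicates: list[MethylomeTable],
    treated_replicates: list[MethylomeTable],
    min_total: int = 0,
) -> dict:
    """Global-level comparison between treatment arms.

    Per-replicate count-weighted global mCG (skimming mode: no coverage
    filter by default), the absolute difference in percentage points, the
    relative depletion 1 - treated/control, and an unpaired two-sided
    pooled-variance t-test across replicates (exact at these replicate
    numbers when arm variances match, which replicated sequencing runs of
    the same design do).  With a single replicate per arm the difference is
    still reported but the test is skipped (flagged).
    """
    lv_c = [global_mcg(m, min_total=min_total).fraction for m in control_replicates]
    lv_t = [global_mcg(m, min_total=min_total).fraction for m in treated_replicates]
    mean_c, mean_t = float(np.mean(lv_c)), float(np.mean(lv_t))
    out = {
        "control_levels": lv_c, "treated_levels": lv_t,
        "difference_pp": (mean_c - mean_t) * 100.0,
        "relative_depletion": 1.0 - mean_t / mean_c if mean_c > 0 else np.nan,
        "tested": False, "t": np.nan, "p": np.nan,
    }
    if len(lv_c) >= 2 and len(lv_t) >= 2:
        t, p = stats.ttest_ind(lv_c, lv_t, equal_var=True)
        out.update(tested=True, t=float(t), p=float(p))
    return out


def aging_trajectory(samples: dict[str, list[MethylomeTable]]) -> pd.DataFrame:
    """Per-age pooled global mCG with binomial CIs from shallow samples.

    All covered CpGs are pooled per age (skimming mode — no per-CpG coverage
    filter); replicate spread is reported alongside a Wilson 95% interval on
    the pooled counts.  The ``monotone_decreasing`` column flags whether the
    age sequence of pooled estimates is non-increasing.
    """
    rows = []
    for age, reps in samples.items():
        n_meth = sum(int(m.records.loc[m.records["context"] == "CG", "n_meth"].sum()) for m in reps)
        n_tot = sum(int(m.records.loc[m.records["context"] == "CG", "n_total"].sum()) for m in reps)
        est = n_meth / n_tot if n_tot else np.nan
        if n_tot:
            lo, hi = stats.binomtest(n_meth, n_tot).proportion_ci(0.95, method="wilson")
        else:
            lo = hi = np.nan
        rep_levels = [global_mcg(m, min_total=0).fraction for m in reps]
        rows.append((age, est, lo, hi, n_tot, float(np.std(rep_levels)) if rep_levels else np.nan))
    df = pd.DataFrame(rows, columns=["age", "global_mcg", "ci_low", "ci_high", "n_calls", "replicate_sd"])
    est = df["global_mcg"].to_numpy()
    df["monotone_decreasing"] = bool(np.all(np.diff(est) <= 0))
    return df
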