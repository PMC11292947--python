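"""Global and positional methylation statistics.

Coverage filtering, global mCG estimation, conversion-error controls, the
genomic CpG observed/expected ratio, and scale-regions metagene profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, MethylomeTable

#: Control contig names the generator and spike-in convention use: a fully
#: unmethylated phage spike (negative control, apparent mCG = non-conversion)
#: and a fully methylated plasmid spike (positive control).
UNMETHYLATED_SPIKE = "lambda_unmeth"
METHYLATED_SPIKE = "pUC19_meth"


@dataclass
class GlobalMethylationEstimate:
    sample_id: str
    fraction: float | None  # None when no CpG passes the filter
    n_cpgs: int
    min_coverage: int
    weighting: str
    nonconversion: float | None = None

    @property
    def defined(self) -> bool:
        return self.fraction is not None


def filter_coverage(methylome: MethylomeTable, min_total: int) -> MethylomeTable:
    """Retain records with count_total strictly greater than ``min_total``.

    The strict reading matches the ">10x coverage" convention used for
    global-level estimates; ``min_total=0`` keeps everything.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    kept = methylome.records[methylome.records["n_total"] > min_total]
    return MethylomeTable(methylome.sample_id, kept.reset_index(drop=True))


def global_mcg(
    methylome: MethylomeTable,
    min_total: int = 10,
    weighting: str = "count",
    exclude_contigs: tuple[str, ...] = (UNMETHYLATED_SPIKE, METHYLATED_SPIKE),
) -> GlobalMethylationEstimate:
    """Global mCG level over CpGs passing the coverage filter.

    ``count`` weighting pools calls (sum methylated / sum total); the
    ``mean_of_fractions`` alternative averages per-CpG fractions.  Spike-in
    control contigs are excluded by default.  With no passing CpG the
    estimate is returned undefined (fraction None, n=0), never silently 0.
    """
    if weighting not in ("count", "mean_of_fractions"):
        raise ValueError(f"unknown weighting {weighting!r}")
    cg = methylome.records[
        (methylome.records["context"] == "CG")
        & ~methylome.records["contig"].isin(exclude_contigs)
    ]
    cg = cg[cg["n_total"] > min_total]
    n = len(cg)
    if n == 0:
        return GlobalMethylationEstimate(methylome.sample_id, None, 0, min_total, weighting)
    if weighting == "count":
        frac = cg["n_meth"].sum() / cg["n_total"].sum()
    else:
        frac = float((cg["n_meth"] / cg["n_total"]).mean())
    return GlobalMethylationEstimate(methylome.sample_id, float(frac), n, min_total, weighting)


def nonconversion_rate(
    methylome: MethylomeTable,
    unmethylated_contigs: tuple[str, ...] = (UNMETHYLATED_SPIKE,),
    methylated_contigs: tuple[str, ...] = (METHYLATED_SPIKE,),
    mito_contig: str | None = None,
) -> dict[str, float | None]:
    """Assay-error controls from spike-ins, mitochondria and non-CpG calls.

    Returns per-class count-weighted apparent methylation: ``spike_unmeth``
    (the headline non-conversion rate), ``spike_meth_excess`` (1 - apparent
    fraction of the methylated spike, the over-conversion control), ``mito``
    and ``non_cpg``.  A missing control class is reported as None.
    """
    df = methylome.records

    def _rate(sub: pd.DataFrame) -> float | None:
        if len(sub) == 0 or sub["n_total"].sum() == 0:
            return None
        return float(sub["n_meth"].sum() / sub["n_total"].sum())

    out: dict[str, float | None] = {}
    out["spike_unmeth"] = _rate(df[df["contig"].isin(unmethylated_contigs)])
    meth = _rate(df[df["contig"].isin(methylated_contigs)])
    out["spike_meth_excess"] = None if meth is None else 1.0 - meth
    out["mito"] = _rate(df[df["contig"] == mito_contig]) if mito_contig else None
    out["non_cpg"] = _rate(df[df["context"].isin(("CHG", "CHH"))])
    return out


def cpg_oe_ratio(sequences: dict[str, str]) -> float:
    """Genomic CpG observed/expected ratio, (#CpG x N) / (#C x #G).

    Dinucleotides are scanned at every offset within each contig (never
    across contig boundaries); ambiguous/non-ACGT bases are excluded from
    all counts and break the dinucleotide scan.  A ratio near 1 indicates a
    CpG composition at equilibrium; depletion (<<1) is the footprint of
    historical germline methylation.
    """
    n_cpg = n_c = n_g = n_tot = 0
    for seq in sequences.values():
        s = seq.upper()
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        n_tot += int(valid.sum())
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        n_c += int(is_c.sum())
        n_g += int(is_g.sum())
        if len(arr) > 1:
            n_cpg += int((is_c[:-1] & is_g[1:]).sum())
    if n_c == 0 or n_g == 0:
        raise ValueError("undefined o/e ratio: no C or no G in sequences")
    return n_cpg * n_tot / (n_c * n_g)


@dataclass
class MetageneMatrix:
    """Per-gene binned mCG over upstream flank, scaled body, downstream flank.

    ``matrix`` rows follow ``gene_ids``; columns are flank bins (fixed width),
    then body bins (gene rescaled), then flank bins again, all oriented so
    column 0 is the 5' upstream end.  Empty bins are NaN.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    n_flank_bins: int
    n_body_bins: int
    flagged: list[str]  # genes shorter than one body bin, excluded from means

    def column_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)

    def body_flank_ratio(self, flank_margin_bins: int = 10) -> float:
        """Mean body signal over mean distal-flank (intergenic proxy) signal.

        The distal flank uses the outermost ``flank_margin_bins`` bins on
        each side, away from the promoter/terminator shoulders.
        """
        means = self.column_means()
        nf, nb = self.n_flank_bins, self.n_body_bins
        body = np.nanmean(means[nf:nf + nb])
        distal = np.nanmean(
            np.concatenate([means[:flank_margin_bins], means[-flank_margin_bins:]])
        )
        return float(body / distal)


def metagene_profile(
    methylome: MethylomeTable,
    annotation: GenomeAnnotation,
    flank: int = 3000,
    body_bins: int = 30,
    flank_bin: int = 100,
) -> MetageneMatrix:
    """Scale-regions metagene matrix of count-weighted mCG.

    Flanks of ``flank`` bases are cut into fixed ``flank_bin``-base bins;
    gene bodies are rescaled to ``body_bins`` bins.  Minus-strand genes are
    reversed so column 0 is always the distal 5' upstream bin.  A bin's
    value is sum(n_meth)/sum(n_total) over the CpGs it contains; bins with
    no covered CpG are NaN and are ignored by :meth:`MetageneMatrix.column_means`.
    """
    cg = methylome.records[methylome.records["context"] == "CG"]
    n_flank_bins = flank // flank_bin
    ncol = 2 * n_flank_bins + body_bins
    by_contig = {c: sub for c, sub in cg.groupby("contig")}
    rows, gene_ids, flagged = [], [], []
    for gid, g in annotation.genes.iterrows():
        start, end, strand = int(g["start"]), int(g["end"]), g["strand"]
        if end - start < body_bins:
            flagged.append(gid)
            continue
        sub = by_contig.get(g["contig"])
        meth = np.zeros(ncol)
        total = np.zeros(ncol)
        if sub is not None:
            pos0 = sub["pos"].to_numpy() - 1  # back to 0-based
            lo, hi = start - flank, end + flank
            m = (pos0 >= lo) & (pos0 < hi)
            p = pos0[m]
            nm = sub["n_meth"].to_numpy()[m]
            nt = sub["n_total"].to_numpy()[m]
            col = np.empty(len(p), dtype=np.int64)
            up = p < start
            down = p >= end
            body = ~up & ~down
            col[up] = (p[up] - lo) // flank_bin
            col[body] = n_flank_bins + (p[body] - start) * body_bins // (end - start)
            col[down] = n_flank_bins + body_bins + (p[down] - end) // flank_bin
            if strand == "-":
                col = ncol - 1 - col
            np.add.at(meth, col, nm)
            np.add.at(total, col, nt)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
        rows.append(row)
        gene_ids.append(gid)
    matrix = np.vstack(rows) if rows else np.empty((0, ncol))
    return MetageneMatrix(matrix, gene_ids, n_flank_bins, body_bins, flagged)
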