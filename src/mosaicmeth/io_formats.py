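"""Readers and writers for the file dialects the pipeline touches.

Coordinate conventions, applied consistently throughout the package:

* per-cytosine positions are 1-based (the CGmap convention); the position of
  a destranded CpG dyad is the position of the cytosine on the plus strand;
* genomic intervals are 0-based half-open internally and at the BED/bedGraph
  boundary; GFF3/GTF input (1-based inclusive) is converted on ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

METH_COLUMNS = ["contig", "pos", "strand", "context", "n_meth", "n_total"]

#: CGmap "context class" column values mapped onto the three cytosine contexts.
_CGMAP_CONTEXTS = {"CG": "CG", "CHG": "CHG", "CHH": "CHH"}


class MethylomeParseError(ValueError):
    """A malformed or invariant-violating line in a methylation call table."""


@dataclass
class MethylomeTable:
    """Per-cytosine methylation calls for one sample.

    ``records`` has columns ``contig, pos, strand, context, n_meth, n_total``
    with 1-based positions, sorted by (contig, pos). ``n_meth <= n_total``
    holds for every row and ``n_total > 0``.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        if list(df.columns) != METH_COLUMNS:
            df = df.reindex(columns=METH_COLUMNS)
        df = df.astype(
            {"contig": str, "pos": np.int64, "strand": str, "context": str,
             "n_meth": np.int64, "n_total": np.int64}
        )
        bad = df["n_meth"] > df["n_total"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise MethylomeParseError(
                f"n_meth > n_total at {df.iloc[i]['contig']}:{df.iloc[i]['pos']}"
            )
        if (df["n_total"] <= 0).any():
            raise MethylomeParseError("records with n_total <= 0")
        df = df.sort_values(["contig", "pos", "strand"], kind="mergesort")
        if df.duplicated(["contig", "pos", "strand"]).any():
            raise MethylomeParseError("duplicate (contig, pos, strand) record")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def fractions(self) -> pd.Series:
        return self.records["n_meth"] / self.records["n_total"]

    def context(self, ctx: str) -> "MethylomeTable":
        """Subset to one cytosine context (CG, CHG or CHH)."""
        sub = self.records[self.records["context"] == ctx]
        return MethylomeTable(self.sample_id, sub.reset_index(drop=True))

    def destrand(self) -> "MethylomeTable":
        """Collapse CG records onto symmetric dyads.

        Counts of a minus-strand CG cytosine at position p are added to the
        plus-strand cytosine at p - 1; non-CG contexts are kept stranded.
        """
        df = self.records.copy()
        cg = df["context"] == "CG"
        minus = cg & (df["strand"] == "-")
        df.loc[minus, "pos"] -= 1
        df.loc[cg, "strand"] = "+"
        out = (
            df.groupby(["contig", "pos", "strand", "context"], as_index=False, sort=False)
            .agg(n_meth=("n_meth", "sum"), n_total=("n_total", "sum"))
        )
        return MethylomeTable(self.sample_id, out.reindex(columns=METH_COLUMNS))


@dataclass
class GenomeAnnotation:
    """Gene models plus contig lengths.

    ``genes``: DataFrame indexed by gene_id with columns
    ``contig, strand, start, end`` (0-based half-open transcript span).
    ``exons``: mapping gene_id -> list of (start, end) half-open intervals,
    non-overlapping and sorted.
    """

    genes: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, exs in self.exons.items():
            g = self.genes.loc[gid]
            last = -1
            for s, e in exs:
                if s < last or s < g["start"] or e > g["end"]:
                    raise ValueError(f"exon ({s},{e}) invalid for gene {gid}")
                last = e

    def introns(self, gene_id: str) -> list[tuple[int, int]]:
        """Half-open intron intervals: the gene-span complement of the exons."""
        exs = self.exons[gene_id]
        out = []
        for (_, e1), (s2, _) in zip(exs, exs[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def tss(self, gene_id: str) -> int:
        """0-based position of the transcription start site (strand-aware)."""
        g = self.genes.loc[gene_id]
        return int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1

    def promoters(self, upstream: int = 2000, downstream: int = 200) -> pd.DataFrame:
        """Strand-aware promoter intervals around each TSS, half-open.

        ``upstream`` bases 5' of the TSS and ``downstream`` bases 3' of it,
        clipped at contig bounds when lengths are known.
        """
        rows = []
        for gid, g in self.genes.iterrows():
            tss = self.tss(gid)
            if g["strand"] == "+":
                s, e = tss - upstream, tss + downstream
            else:
                s, e = tss - downstream + 1, tss + upstream + 1
            s = max(s, 0)
            clen = self.contig_lengths.get(g["contig"])
            if clen is not None:
                e = min(e, clen)
            rows.append((g["contig"], s, e, gid))
        return pd.DataFrame(rows, columns=["contig", "start", "end", "label"])


@dataclass
class RegionSet:
    """A labelled set of half-open genomic intervals (may overlap)."""

    intervals: pd.DataFrame  # columns contig, start, end, label

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        if list(df.columns) != ["contig", "start", "end", "label"]:
            df = df.reindex(columns=["contig", "start", "end", "label"])
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("interval with start >= end")
        self.intervals = df.sort_values(["contig", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


def read_cgmap(path, sample_id: str | None = None, destrand: bool = True) -> MethylomeTable:
    """Read an 8-column CGmap file into a :class:`MethylomeTable`.

    Columns: contig, nucleotide (C/G), 1-based position, context class,
    dinucleotide context, methylation fraction, count methylated, count total.
    Strand is inferred from the nucleotide (C -> +, G -> -).  With
    ``destrand`` (default) CG dyads are collapsed onto the plus-strand C.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise MethylomeParseError(f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
            contig, nuc, pos, ctx, _dinuc, _frac, n_meth, n_total = parts
            if nuc not in ("C", "G"):
                raise MethylomeParseError(f"{path}:{lineno}: nucleotide must be C or G")
            if ctx not in _CGMAP_CONTEXTS:
                warnings.warn(f"{path}:{lineno}: unknown context {ctx!r}, dropped")
                continue
            try:
                pos, n_meth, n_total = int(pos), int(n_meth), int(n_total)
            except ValueError as exc:
                raise MethylomeParseError(f"{path}:{lineno}: non-integer field") from exc
            if n_meth > n_total:
                raise MethylomeParseError(
                    f"{path}:{lineno}: count_methylated {n_meth} > count_total {n_total}"
                )
            if n_total <= 0:
                continue
            strand = "+" if nuc == "C" else "-"
            rows.append((contig, pos, strand, _CGMAP_CONTEXTS[ctx], n_meth, n_total))
    name = sample_id or str(path)
    table = MethylomeTable(name, pd.DataFrame(rows, columns=METH_COLUMNS))
    return table.destrand() if destrand else table


def write_cgmap(methylome: MethylomeTable, path, header: str | None = None) -> None:
    """Write a table back to the 8-column CGmap layout (counts preserved)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for r in methylome.records.itertuples(index=False):
            nuc = "C" if r.strand == "+" else "G"
            dinuc = {"CG": "CG", "CHG": "CA", "CHH": "CA"}[r.context]
            frac = r.n_meth / r.n_total
            fh.write(
                f"{r.contig}\t{nuc}\t{r.pos}\t{r.context}\t{dinuc}\t{frac:.4f}\t{r.n_meth}\t{r.n_total}\n"
            )


def read_coverage(path, sample_id: str | None = None, destrand: bool = False) -> MethylomeTable:
    """Read a 6-column bisulfite coverage file.

    Columns: chrom, start, end (both 1-based inclusive), methylation
    percentage, count methylated, count unmethylated.  The counts are
    authoritative: if the stated percentage disagrees beyond 0.5 points a
    warning is issued and the counts win.  Context is CG and strand + (the
    dialect carries neither).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise MethylomeParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            contig, pos, _end, pct, n_m, n_u = parts
            try:
                pos, n_m, n_u, pct = int(pos), int(n_m), int(n_u), float(pct)
            except ValueError as exc:
                raise MethylomeParseError(f"{path}:{lineno}: bad numeric field") from exc
            total = n_m + n_u
            if total == 0:
                continue
            if abs(100.0 * n_m / total - pct) > 0.5:
                warnings.warn(
                    f"{path}:{lineno}: stated {pct}% disagrees with counts {n_m}/{total}; counts win"
                )
            rows.append((contig, pos, "+", "CG", n_m, total))
    name = sample_id or str(path)
    table = MethylomeTable(name, pd.DataFrame(rows, columns=METH_COLUMNS))
    return table.destrand() if destrand else table


def read_gene_models(path, contig_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read gene models from GFF3 or GTF into a :class:`GenomeAnnotation`.

    For each gene the exon set of its longest transcript is kept (merged to
    non-overlapping intervals); a gene feature without transcripts is treated
    as single-exon.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, disable_infer_genes=True, disable_infer_transcripts=True,
    )
    gene_rows: list[tuple] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        gstart, gend = gene.start - 1, gene.end  # to half-open
        best_exons: list[tuple[int, int]] | None = None
        best_span = -1
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            exs = sorted(
                (e.start - 1, e.end) for e in db.children(tx, featuretype="exon", level=1)
            )
            span = tx.end - tx.start + 1
            if exs and span > best_span:
                best_span, best_exons = span, exs
        if best_exons is None:
            best_exons = [(gstart, gend)]
        merged: list[tuple[int, int]] = []
        for s, e in best_exons:
            if s < gstart or e > gend:
                raise ValueError(f"exon ({s},{e}) outside span of gene {gid}")
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        gene_rows.append((gid, gene.seqid, gene.strand, gstart, gend))
        exons[gid] = merged
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "contig", "strand", "start", "end"]
    ).set_index("gene_id")
    return GenomeAnnotation(genes, exons, contig_lengths or {})


def read_regions_bed(path) -> RegionSet:
    """Read a BED4 file (0-based half-open) into a :class:`RegionSet`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MethylomeParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise MethylomeParseError(f"{path}:{lineno}: start >= end")
            label = parts[3] if len(parts) > 3 else f"region_{lineno}"
            rows.append((contig, start, end, label))
    return RegionSet(pd.DataFrame(rows, columns=["contig", "start", "end", "label"]))


def write_regions_bed(regions: RegionSet, path) -> None:
    regions.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a gene x stage TPM matrix (TSV, first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MethylomeParseError(f"{path}: non-numeric TPM value") from exc
    if (df < 0).any().any():
        raise MethylomeParseError(f"{path}: negative TPM value")
    return df


def read_orthologues(path, known_ids1=None, known_ids2=None) -> pd.DataFrame:
    """Read a two-column one-to-one orthologue table.

    Unknown gene ids (when the annotations' id sets are given) are retained
    with ``known=False`` so callers can decide how to treat them.
    """
    pairs = pd.read_csv(path, sep="\t", header=None, names=["gene1", "gene2"], dtype=str)
    known = pd.Series(True, index=pairs.index)
    if known_ids1 is not None:
        known &= pairs["gene1"].isin(set(known_ids1))
    if known_ids2 is not None:
        known &= pairs["gene2"].isin(set(known_ids2))
    pairs["known"] = known
    return pairs


def binned_track(methylome: MethylomeTable, bin_size: int = 75) -> pd.DataFrame:
    """Count-weighted mCG per fixed-size genome bin (0-based half-open).

    The 75-base default matches genome-browser methylation tracks.  Bins with
    no covered CpG are omitted; values are in [0, 1].
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    cg = methylome.records[methylome.records["context"] == "CG"]
    rows = []
    for contig, sub in cg.groupby("contig", sort=True):
        bins = (sub["pos"].to_numpy() - 1) // bin_size
        agg = sub.assign(bin=bins).groupby("bin")[["n_meth", "n_total"]].sum()
        for b, r in agg.iterrows():
            rows.append((contig, int(b) * bin_size, (int(b) + 1) * bin_size,
                         r["n_meth"] / r["n_total"]))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "value"])


def write_binned_track(methylome: MethylomeTable, path, bin_size: int = 75) -> None:
    """Write the binned methylation track as sorted bedGraph."""
    track = binned_track(methylome, bin_size)
    with open(path, "w") as fh:
        for r in track.itertuples(index=False):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.value:.6g}\n")
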