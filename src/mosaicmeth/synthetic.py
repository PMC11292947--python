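"""Synthetic mosaic-methylome generator with a planted truth table.

Emulates the statistical structure an invertebrate mosaic methylome analysis
assumes: per-CpG binomial counts around compartment targets (gene bodies,
hypomethylated upstream promoters, transposable elements, intergenic
background), gene-body methylation coupled to expression level (positive,
monotone) and to expression variability (negative), stage-wise global
erosion, planted differentially methylated regions, spike-in control contigs
with known conversion error, stochastic treatment depletion, and
shallow-coverage "skimming" replicates.  The planted parameters are kept in
a :class:`SyntheticTruth` so downstream estimators can be scored against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import METH_COLUMNS, GenomeAnnotation, MethylomeTable, RegionSet
from .core import METHYLATED_SPIKE, UNMETHYLATED_SPIKE

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Stage-wise global erosion factors (relative to the embryonic level).  The
#: default trajectory mirrors a life cycle whose adult methylome has eroded
#: to roughly 58% of the gastrula level while the larva is nearly unchanged.
DEFAULT_STAGES = ("gastrula", "larva", "adult")
DEFAULT_EROSION = (1.0, 0.98, 0.58)

#: Age series for the shallow-sequencing aging analysis (erosion factors
#: applied on top of the adult-like base level).
DEFAULT_AGE_EROSION = {"larva_st8": 0.9, "juvenile_1m": 0.8, "adult": 0.7, "senescent_22w": 0.5}


class SizingError(ValueError):
    """Requested features do not fit in the requested genome."""


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _spawn(seed, n):
    return np.random.SeedSequence(seed).spawn(n)


def generate_genome(
    n_contigs: int = 2,
    contig_length: int = 1_000_000,
    n_genes: int = 400,
    n_tes: int = 300,
    seed: int = 0,
    gc: float = 0.42,
    gene_length: tuple[int, int] = (800, 2500),
    min_gap: int = 1500,
    max_exons: int = 6,
    te_length=(150, 1200),
    n_atac_distal: int | None = None,
) -> tuple[dict[str, str], GenomeAnnotation, RegionSet, RegionSet]:
    """Random genome with non-overlapping genes, TEs and ATAC peaks.

    Sequences are i.i.d. with the given GC content, so CpG sites arise at
    their random-expectation density.  Genes are tiled with at least
    ``min_gap`` intergenic bases between them; TEs are split evenly between
    introns and intergenic space, with lengths straddling the downstream
    400 bp filter; ATAC peaks cover a subset of promoters plus distal
    intergenic sites.  Deterministic for a fixed seed.
    """
    if min(n_contigs, contig_length) <= 0 or n_genes < 0 or n_tes < 0:
        raise ValueError("genome parameters must be positive")
    ss = _spawn(seed, 5)
    rng_seq, rng_gene, rng_te, rng_atac, _ = (np.random.default_rng(s) for s in ss)

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences = {
        f"contig_{i + 1}": BASES[rng_seq.choice(4, size=contig_length, p=p)].tobytes().decode()
        for i in range(n_contigs)
    }
    contigs = list(sequences)
    contig_lengths = {c: contig_length for c in contigs}

    # tile genes round-robin across contigs
    per_contig = [n_genes // n_contigs + (1 if i < n_genes % n_contigs else 0)
                  for i in range(n_contigs)]
    gene_rows, exons = [], {}
    gid_counter = 0
    for ci, contig in enumerate(contigs):
        cursor = min_gap
        for _ in range(per_contig[ci]):
            glen = int(rng_gene.integers(gene_length[0], gene_length[1] + 1))
            gap = int(rng_gene.integers(min_gap, 2 * min_gap + 1))
            start = cursor + gap
            end = start + glen
            if end + min_gap > contig_length:
                raise SizingError(
                    f"{n_genes} genes of {gene_length} bp with gap >= {min_gap} "
                    f"do not fit in {n_contigs} x {contig_length} bp"
                )
            gid_counter += 1
            gid = f"g{gid_counter:05d}"
            strand = "+" if rng_gene.random() < 0.5 else "-"
            n_ex = int(rng_gene.integers(1, max_exons + 1))
            n_ex = min(n_ex, max(1, glen // 300))
            cuts = np.sort(rng_gene.choice(np.arange(start + 50, end - 50), size=2 * (n_ex - 1),
                                           replace=False)) if n_ex > 1 else np.array([], dtype=int)
            bounds = np.concatenate([[start], cuts, [end]])
            exs = [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_ex)]
            exs = [(s, e) for s, e in exs if e > s] or [(start, end)]
            gene_rows.append((gid, contig, strand, start, end))
            exons[gid] = exs
            cursor = end
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "contig", "strand", "start", "end"]
                         ).set_index("gene_id")
    annotation = GenomeAnnotation(genes, exons, contig_lengths)

    # TEs: half intronic, half intergenic, non-overlapping with each other
    def _te_len() -> int:
        if isinstance(te_length, (list, set, frozenset)):
            return int(rng_te.choice(sorted(te_length)))
        return int(rng_te.integers(te_length[0], te_length[1] + 1))

    te_rows: list[tuple] = []
    genic_genes = [g for g in genes.index if len(annotation.introns(g)) > 0]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}

    def _free(contig, s, e) -> bool:
        return all(e <= os or s >= oe for os, oe in occupied[contig])

    families = ["LTR", "LINE", "DNA", "SINE"]
    attempts = 0
    while len(te_rows) < n_tes and attempts < n_tes * 60:
        attempts += 1
        k = len(te_rows)
        L = _te_len()
        if k % 2 == 0 and genic_genes:
            gid = genic_genes[int(rng_te.integers(len(genic_genes)))]
            g = genes.loc[gid]
            introns = [iv for iv in annotation.introns(gid) if iv[1] - iv[0] > L + 10]
            if not introns:
                continue
            s0, e0 = introns[int(rng_te.integers(len(introns)))]
            s = int(rng_te.integers(s0, e0 - L))
            contig = g["contig"]
        else:
            contig = contigs[int(rng_te.integers(n_contigs))]
            s = int(rng_te.integers(0, contig_length - L))
            # stay out of gene spans for the intergenic half
            sub = genes[genes["contig"] == contig]
            if ((s < sub["end"]) & (s + L > sub["start"])).any():
                continue
        if not _free(contig, s, s + L):
            continue
        occupied[contig].append((s, s + L))
        fam = families[int(rng_te.integers(len(families)))]
        te_rows.append((contig, s, s + L, f"TE{k + 1:05d}#{fam}"))
    if len(te_rows) < n_tes:
        raise SizingError(f"could only place {len(te_rows)} of {n_tes} TEs")
    tes = RegionSet(pd.DataFrame(te_rows, columns=["contig", "start", "end", "label"])) \
        if te_rows else RegionSet(pd.DataFrame(columns=["contig", "start", "end", "label"]))

    # ATAC peaks: half the promoters, plus distal intergenic peaks
    atac_rows = []
    for gid, g in genes.iterrows():
        if rng_atac.random() < 0.5:
            tss = annotation.tss(gid)
            atac_rows.append((g["contig"], max(0, tss - 250), tss + 250, f"atac_{gid}"))
    n_distal = n_atac_distal if n_atac_distal is not None else n_genes // 4
    placed = 0
    attempts = 0
    while placed < n_distal and attempts < n_distal * 50:
        attempts += 1
        contig = contigs[int(rng_atac.integers(n_contigs))]
        s = int(rng_atac.integers(0, contig_length - 400))
        sub = genes[genes["contig"] == contig]
        if ((s - 2000 < sub["end"]) & (s + 2400 > sub["start"])).any():
            continue
        placed += 1
        atac_rows.append((contig, s, s + 400, f"atac_distal_{placed}"))
    atac = RegionSet(pd.DataFrame(atac_rows, columns=["contig", "start", "end", "label"])) \
        if atac_rows else RegionSet(pd.DataFrame(columns=["contig", "start", "end", "label"]))
    return sequences, annotation, tes, atac


def cpg_sites(sequences: dict[str, str]) -> dict[str, np.ndarray]:
    """0-based positions of the C of every CpG dinucleotide, per contig."""
    out = {}
    for contig, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        out[contig] = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    return out


def _interval_index(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Index of the (sorted, non-overlapping) interval containing each position, else -1."""
    if len(starts) == 0:
        return np.full(len(positions), -1, dtype=np.int64)
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
    return np.where(ok, idx, -1)


@dataclass
class SyntheticTruth:
    """Planted generator parameters: the oracle for all recovery tests."""

    seed: int
    annotation: GenomeAnnotation
    tes: RegionSet
    stages: tuple[str, ...]
    erosion: dict[str, float]
    gene_params: pd.DataFrame           # expr_mean, expr_cv, nonexpressed, target_gbm
    gene_targets: pd.DataFrame          # genes x stages target body methylation
    background_level: float
    umr_level: float
    te_level: float
    te_mode: bool
    umrs: pd.DataFrame                  # contig, start, end, gene_id
    dmrs: pd.DataFrame                  # contig, start, end, n_cpgs
    dmr_levels: dict[str, np.ndarray]
    spike_nonconversion: float = 0.01
    spike_overconversion: float = 0.005
    depletion_fraction: float = 0.042
    expression: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    age_erosion: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_EROSION))
    # per-contig CpG maps (0-based)
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    _gene_index: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _te_mask: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _umr_mask: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _dmr_index: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    non_cg_positions: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    gene_order: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        ero = [self.erosion[s] for s in self.stages]
        if any(b > a for a, b in zip(ero, ero[1:])):
            raise ValueError("erosion factors must be non-increasing across stages")
        for df in (self.gene_targets,):
            if ((df < 0) | (df > 1)).any().any():
                raise ValueError("target fractions must lie in [0, 1]")
        if len(self.dmrs):
            if (self.dmrs["n_cpgs"] < 5).any():
                raise ValueError("every planted DMR needs >= 5 CpGs")
            levels = np.vstack([self.dmr_levels[s] for s in self.stages])
            if (np.ptp(levels, axis=0) < 0.2 - 1e-9).any():
                raise ValueError("planted DMR between-stage difference must be >= 0.2")

    # -- per-CpG expected (apparent) methylation ---------------------------
    def cpg_expected(self, stage: str | None = None, erosion_factor: float | None = None,
                     conversion_error: bool = True) -> dict[str, np.ndarray]:
        """Expected apparent mCG per CpG site for a stage (or explicit factor).

        Compartment precedence: planted DMR > promoter UMR > TE (in
        TE-methylating mode) > gene body > intergenic background; the result
        is scaled by the stage's erosion factor and, when requested, passed
        through the conversion-error observation model.
        """
        if erosion_factor is None:
            erosion_factor = self.erosion[stage] if stage is not None else 1.0
        if stage is None:
            stage = self.stages[0]
        targets = self.gene_targets[stage].to_numpy()
        out = {}
        for contig, pos in self.cpg_positions.items():
            p = np.full(len(pos), self.background_level)
            gi = self._gene_index[contig]
            has = gi >= 0
            p[has] = targets[gi[has]]
            if self.te_mode:
                p[self._te_mask[contig]] = self.te_level
            p[self._umr_mask[contig]] = self.umr_level
            di = self._dmr_index[contig]
            dm = di >= 0
            if dm.any():
                p[dm] = self.dmr_levels[stage][di[dm]]
            p = np.clip(p * erosion_factor, 0.0, 1.0)
            if conversion_error:
                p = p * (1 - self.spike_overconversion) + self.spike_nonconversion * (1 - p)
            out[contig] = p
        return out

    def expected_global(self, stage: str | None = None, erosion_factor: float | None = None) -> float:
        exp = self.cpg_expected(stage, erosion_factor)
        tot = sum(len(v) for v in exp.values())
        return float(sum(v.sum() for v in exp.values()) / tot)

    def expected_gbm(self, stage: str) -> pd.Series:
        """Expected per-gene body methylation (mean apparent mCG over body CpGs)."""
        exp = self.cpg_expected(stage)
        sums = np.zeros(len(self.gene_order))
        counts = np.zeros(len(self.gene_order))
        for contig, p in exp.items():
            gi = self._gene_index[contig]
            has = gi >= 0
            np.add.at(sums, gi[has], p[has])
            np.add.at(counts, gi[has], 1.0)
        with np.errstate(invalid="ignore"):
            return pd.Series(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan),
                             index=self.gene_order)


def make_truth(
    sequences: dict[str, str],
    annotation: GenomeAnnotation,
    tes: RegionSet,
    seed: int = 0,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    erosion: tuple[float, ...] = DEFAULT_EROSION,
    expression_link: bool = True,
    cv_link: bool = True,
    gbm_range: tuple[float, float] = (0.08, 0.80),
    cv_span: float = 0.45,
    gbm_noise: float = 0.04,
    nonexpressed_fraction: float = 0.10,
    expr_stages: int = 8,
    body_intergenic_ratio: float = 1.15,
    background_level: float | None = None,
    umr_level: float = 0.02,
    promoter_umr_span: int = 600,
    umr_min_cpgs: int = 6,
    n_umrs: int | None = None,
    te_mode: bool = True,
    te_level: float = 0.70,
    n_dmrs: int = 0,
    dmr_delta: float = 0.35,
    dmr_n_cpgs: int = 8,
    stage_link_weights: dict[str, float] | None = None,
    stage_gene_shift: dict[str, pd.Series] | None = None,
    spike_nonconversion: float = 0.01,
    spike_overconversion: float = 0.005,
    depletion_fraction: float = 0.042,
) -> SyntheticTruth:
    """Draw the planted truth for a generated genome.

    Per-gene target body methylation follows a monotone (logistic plus
    linear) link to the gene's expression decile and a negative linear link
    to its expression-variability decile, with additive noise; non-expressed
    genes sit at the low end.  The intergenic background level is set so the
    CpG-weighted gene-body mean exceeds it by ``body_intergenic_ratio``
    (pass ``background_level`` to override, e.g. for a hypermethylated
    validation genome).  Upstream promoter windows are planted unmethylated;
    optional DMRs are planted in CpG-dense intergenic windows with the given
    between-stage contrast.
    """
    if len(stages) != len(erosion):
        raise ValueError("stages and erosion lengths differ")
    genes = annotation.genes
    n = len(genes)
    ss = _spawn(seed, 6)
    rng_expr, rng_gbm, rng_stage, rng_dmr, rng_misc, _ = (np.random.default_rng(s) for s in ss)

    # expression parameters: level and variability are negatively correlated
    # latents (highly expressed genes tend to be transcriptionally stable)
    rho = -0.8
    z_e = rng_expr.normal(size=n)
    z_c = rho * z_e + np.sqrt(1 - rho ** 2) * rng_expr.normal(size=n)
    drawn_nonexp = rng_expr.random(n) < nonexpressed_fraction
    mean_tpm = np.where(drawn_nonexp, rng_expr.uniform(0.05, 0.6, n), np.exp(2.0 + 1.2 * z_e))
    cv = np.exp(np.log(0.5) + 0.8 * z_c)

    # the expression matrix itself is part of the truth: the methylation
    # target tracks each gene's realized expression trajectory
    stage_cols = list(stages) + [f"st{k + 1}" for k in range(len(stages), expr_stages)]
    matrix = _draw_expression(mean_tpm, cv, len(stage_cols), rng_expr)
    expression = pd.DataFrame(matrix, index=genes.index, columns=stage_cols)
    real_mean = expression.mean(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        real_cv = np.where(real_mean > 0, expression.std(axis=1, ddof=1).to_numpy() / real_mean, 0.0)
    nonexp = real_mean < 1.0

    # uniform rank scores of the realized summaries drive the two links
    u_e = (np.argsort(np.argsort(real_mean, kind="stable"), kind="stable") + 0.5) / n
    u_c = (np.argsort(np.argsort(real_cv, kind="stable"), kind="stable") + 0.5) / n

    lo, hi = gbm_range
    span = hi - lo
    link = u_e
    base = lo + span * (link if expression_link else 0.5)
    if cv_link:
        base = base - cv_span * (u_c - 0.5)
    base = np.where(nonexp, lo * 0.8, base)
    target = np.clip(base + rng_gbm.normal(0, gbm_noise, n), 0.02, 0.95)

    gene_targets = {}
    tmean, tsd = float(target.mean()), float(target.std())
    for s in stages:
        w = 1.0 if stage_link_weights is None else float(stage_link_weights.get(s, 1.0))
        if w >= 1.0:
            t = target.copy()
        else:
            fresh = rng_stage.normal(0, 1, n)
            t = tmean + w * (target - tmean) + np.sqrt(max(0.0, 1 - w * w)) * tsd * fresh
        if stage_gene_shift and s in stage_gene_shift:
            t = t + stage_gene_shift[s].reindex(genes.index).fillna(0.0).to_numpy()
        gene_targets[s] = np.clip(t, 0.0, 0.98)
    gene_targets = pd.DataFrame(gene_targets, index=genes.index)

    gene_params = pd.DataFrame(
        {"expr_mean": mean_tpm, "expr_cv": cv, "real_mean": real_mean, "real_cv": real_cv,
         "nonexpressed": nonexp, "target_gbm": target},
        index=genes.index,
    )

    cpg_pos = cpg_sites(sequences)

    # promoter UMRs: strand-aware upstream window, clipped at neighbouring
    # gene bodies so a planted promoter never erases a neighbour's body
    umr_rows = []
    spans = {c: sub.sort_values("start")[["start", "end"]].to_numpy()
             for c, sub in genes.groupby("contig")}
    for gid, g in genes.iterrows():
        tss = annotation.tss(gid)
        if g["strand"] == "+":
            s_, e_ = max(0, tss - promoter_umr_span), tss
        else:
            s_, e_ = tss + 1, tss + 1 + promoter_umr_span
        for os_, oe_ in spans[g["contig"]]:
            if os_ == g["start"] and oe_ == g["end"]:
                continue
            if oe_ <= e_ and oe_ > s_:
                s_ = int(oe_)
            if os_ >= s_ and os_ < e_:
                e_ = int(os_)
        if e_ <= s_:
            continue
        pos = cpg_pos[g["contig"]]
        k = int(np.searchsorted(pos, e_) - np.searchsorted(pos, s_))
        if k >= umr_min_cpgs:
            umr_rows.append((g["contig"], s_, e_, gid))
    if n_umrs is not None and len(umr_rows) > n_umrs:
        keep = rng_misc.choice(len(umr_rows), size=n_umrs, replace=False)
        umr_rows = [umr_rows[i] for i in sorted(keep)]
    umrs = pd.DataFrame(umr_rows, columns=["contig", "start", "end", "gene_id"])

    # compartment caches
    gene_index, te_mask, umr_mask, dmr_index = {}, {}, {}, {}
    gene_order = list(genes.index)
    gpos = {gid: i for i, gid in enumerate(gene_order)}
    for contig, pos in cpg_pos.items():
        sub = genes[genes["contig"] == contig].sort_values("start")
        gi = _interval_index(pos, sub["start"].to_numpy(), sub["end"].to_numpy())
        remap = np.array([gpos[g] for g in sub.index], dtype=np.int64) if len(sub) else np.array([], dtype=np.int64)
        gene_index[contig] = np.where(gi >= 0, remap[np.clip(gi, 0, None)], -1)
        tsub = tes.intervals[tes.intervals["contig"] == contig].sort_values("start")
        ti = _interval_index(pos, tsub["start"].to_numpy(), tsub["end"].to_numpy())
        te_mask[contig] = ti >= 0
        usub = umrs[umrs["contig"] == contig].sort_values("start")
        ui = _interval_index(pos, usub["start"].to_numpy(), usub["end"].to_numpy())
        umr_mask[contig] = ui >= 0
        dmr_index[contig] = np.full(len(pos), -1, dtype=np.int64)

    # planted DMRs: CpG-dense intergenic windows, alternating direction
    dmr_rows, dmr_lv = [], []
    if n_dmrs > 0:
        candidates = []
        for contig, pos in cpg_pos.items():
            free = (gene_index[contig] < 0) & ~te_mask[contig] & ~umr_mask[contig]
            for i in range(0, len(pos) - dmr_n_cpgs):
                j = i + dmr_n_cpgs - 1
                if not free[i:j + 1].all():
                    continue
                if pos[j] - pos[i] > 700 or np.diff(pos[i:j + 1]).max() > 80:
                    continue
                candidates.append((contig, i, j))
        # keep well-separated candidates
        chosen, last = [], {}
        for contig, i, j in candidates:
            if contig in last and cpg_pos[contig][i] - last[contig] < 3000:
                continue
            chosen.append((contig, i, j))
            last[contig] = cpg_pos[contig][j]
        if len(chosen) < n_dmrs:
            raise SizingError(f"only {len(chosen)} intergenic CpG-dense DMR sites available")
        pick = sorted(rng_dmr.choice(len(chosen), size=n_dmrs, replace=False))
        base_level = background_level if background_level is not None else 0.30
        for k, ci in enumerate(pick):
            contig, i, j = chosen[ci]
            dmr_index[contig][i:j + 1] = k
            start, end = int(cpg_pos[contig][i]), int(cpg_pos[contig][j]) + 2
            dmr_rows.append((contig, start, end, j - i + 1))
            if k % 2 == 0:  # hyper in later stages
                lv = (base_level, min(0.95, base_level + dmr_delta))
            else:
                hi_ = min(0.9, base_level + dmr_delta)
                lv = (hi_, hi_ - dmr_delta)
            dmr_lv.append(lv)
    dmrs = pd.DataFrame(dmr_rows, columns=["contig", "start", "end", "n_cpgs"])
    if dmr_lv:
        arr = np.array(dmr_lv)
        dmr_levels = {s: (arr[:, 0] if si == 0 else arr[:, 1]) for si, s in enumerate(stages[:2])}
        for s in stages[2:]:
            dmr_levels[s] = arr[:, 1]
    else:
        dmr_levels = {s: np.array([]) for s in stages}

    # background from the requested body/background contrast
    if background_level is None:
        body_p = []
        t0 = gene_targets[stages[0]].to_numpy()
        for contig in cpg_pos:
            gi = gene_index[contig]
            has = gi >= 0
            p = t0[gi[has]].copy()
            if te_mode:
                p[te_mask[contig][has]] = te_level
            p[umr_mask[contig][has]] = umr_level
            body_p.append(p)
        body_mean = float(np.concatenate(body_p).mean()) if body_p else 0.3
        background_level = body_mean / body_intergenic_ratio

    # a small sample of non-CpG cytosines for conversion-rate estimation
    non_cg = {}
    for contig, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        cs = np.flatnonzero(arr == ord("C"))
        cs = np.setdiff1d(cs, cpg_pos[contig], assume_unique=True)
        take = min(len(cs), 2500)
        non_cg[contig] = np.sort(rng_misc.choice(cs, size=take, replace=False)) if take else cs

    return SyntheticTruth(
        seed=seed, annotation=annotation, tes=tes, stages=tuple(stages),
        erosion=dict(zip(stages, erosion)), gene_params=gene_params,
        gene_targets=gene_targets, background_level=float(background_level),
        umr_level=umr_level, te_level=te_level, te_mode=te_mode,
        umrs=umrs, dmrs=dmrs, dmr_levels=dmr_levels,
        spike_nonconversion=spike_nonconversion, spike_overconversion=spike_overconversion,
        depletion_fraction=depletion_fraction, expression=expression,
        cpg_positions=cpg_pos, _gene_index=gene_index, _te_mask=te_mask,
        _umr_mask=umr_mask, _dmr_index=dmr_index, non_cg_positions=non_cg,
        gene_order=gene_order,
    )


def _draw_expression(mean: np.ndarray, cv: np.ndarray, n_stages: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Log-normal stage draws with the given per-gene mean and CV."""
    sigma2 = np.log1p(np.asarray(cv, dtype=float) ** 2)
    mu = np.log(np.maximum(mean, 1e-12)) - sigma2 / 2
    vals = np.exp(mu[:, None] + np.sqrt(sigma2)[:, None] * rng.normal(size=(len(mean), n_stages)))
    return np.where(np.asarray(cv)[:, None] == 0, np.asarray(mean)[:, None], vals)


def generate_expression(truth: SyntheticTruth, seed: int = 0,
                        stages: tuple[str, ...] | None = None,
                        cv: np.ndarray | float | None = None) -> pd.DataFrame:
    """Gene x stage TPM matrix for a truth table.

    With no arguments this returns the expression trajectory that is itself
    part of the truth (the one the methylation targets track).  Passing
    ``stages`` (and optionally a ``cv`` override, scalar or per-gene) draws
    a fresh log-normal matrix around the planted per-gene mean TPM and CV;
    CV 0 degenerates to a constant.  Deterministic for a seed.
    """
    if stages is None and cv is None:
        return truth.expression.copy()
    stages = tuple(stages or truth.expression.columns)
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    rng = _rng(seed)
    mean = truth.gene_params["expr_mean"].to_numpy()
    cv_arr = truth.gene_params["expr_cv"].to_numpy() if cv is None else np.broadcast_to(
        np.asarray(cv, dtype=float), (len(mean),))
    vals = _draw_expression(mean, cv_arr, len(stages), rng)
    return pd.DataFrame(vals, index=truth.gene_params.index, columns=list(stages))


def _spike_records(truth: SyntheticTruth, mean_depth: float, rng: np.random.Generator) -> list[tuple]:
    rows = []
    for contig, n_sites, p in (
        (UNMETHYLATED_SPIKE, 400, truth.spike_nonconversion),
        (METHYLATED_SPIKE, 200, 1.0 - truth.spike_overconversion),
    ):
        depth = rng.poisson(mean_depth, n_sites)
        meth = rng.binomial(depth, p)
        for i in range(n_sites):
            if depth[i] > 0:
                rows.append((contig, 10 * (i + 1), "+", "CG", int(meth[i]), int(depth[i])))
    return rows


def generate_methylome(
    truth: SyntheticTruth,
    stage: str,
    mean_depth: float = 30.0,
    seed: int = 0,
    include_spikes: bool = True,
    include_non_cg: bool = True,
    erosion_factor: float | None = None,
    sample_id: str | None = None,
) -> MethylomeTable:
    """One sample's per-CpG call table at a stage.

    Totals are Poisson around ``mean_depth`` (zero-depth sites omitted);
    methylated counts are binomial around the site's expected apparent
    fraction, which already includes the stage erosion and the conversion
    error of the assay.  Spike-in control contigs and a thin sample of
    non-CpG cytosine records are appended for conversion-rate estimation.
    The emitted table is destranded (one record per CpG dyad).
    """
    rng = _rng(seed)
    expected = truth.cpg_expected(stage, erosion_factor=erosion_factor)
    frames = []
    for contig, pos in truth.cpg_positions.items():
        p = expected[contig]
        depth = rng.poisson(mean_depth, len(pos))
        keep = depth > 0
        meth = rng.binomial(depth[keep], p[keep])
        frames.append(pd.DataFrame({
            "contig": contig, "pos": pos[keep] + 1, "strand": "+", "context": "CG",
            "n_meth": meth, "n_total": depth[keep],
        }))
    rows = []
    if include_non_cg:
        nc = truth.spike_nonconversion
        for contig, pos in truth.non_cg_positions.items():
            depth = rng.poisson(mean_depth, len(pos))
            keep = depth > 0
            meth = rng.binomial(depth[keep], nc)
            ctx = np.where(rng.random(int(keep.sum())) < 0.5, "CHG", "CHH")
            frames.append(pd.DataFrame({
                "contig": contig, "pos": pos[keep] + 1, "strand": "+", "context": ctx,
                "n_meth": meth, "n_total": depth[keep],
            }))
    if include_spikes:
        rows += _spike_records(truth, mean_depth, rng)
    if rows:
        frames.append(pd.DataFrame(rows, columns=METH_COLUMNS))
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=METH_COLUMNS)
    name = sample_id or f"sim_{stage}_seed{seed}"
    return MethylomeTable(name, records)


def apply_global_depletion(methylome: MethylomeTable, fraction: float, seed: int = 0) -> MethylomeTable:
    """Stochastic genome-wide loss of methylated calls.

    Each methylated count is thinned binomially with keep probability
    ``1 - fraction``; totals are unchanged, so the expected global mCG drops
    by exactly the given relative fraction, uniformly (no region targeted) —
    the signature of DNMT-sequestration treatments.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = _rng(seed)
    df = methylome.records.copy()
    df["n_meth"] = rng.binomial(df["n_meth"].to_numpy(), 1.0 - fraction)
    return MethylomeTable(methylome.sample_id + f"_depleted{fraction:g}", df)


def generate_skimming_series(
    truth: SyntheticTruth,
    ages: list[str] | None = None,
    reads_per_sample: int = 20_000,
    n_replicates: int = 2,
    seed: int = 0,
) -> dict[str, list[MethylomeTable]]:
    """Shallow-coverage replicate series across ages (genome-skimming mode).

    Per-CpG depth is Poisson with mean ``reads_per_sample / n_CpGs`` (mostly
    0 or 1), so a sample's realized total call count is Poisson around
    ``reads_per_sample``.  Age erosion factors come from the truth and must
    follow its (strictly ordered) age map.
    """
    ages = list(ages or truth.age_erosion)
    factors = [truth.age_erosion[a] for a in ages]
    if any(b >= a for a, b in zip(factors, factors[1:])):
        raise ValueError("age erosion factors must be strictly decreasing")
    n_cpg = sum(len(v) for v in truth.cpg_positions.values())
    lam = reads_per_sample / n_cpg
    out: dict[str, list[MethylomeTable]] = {}
    seeds = iter(_spawn(seed, len(ages) * n_replicates))
    for age in ages:
        out[age] = []
        expected = truth.cpg_expected(stage=None, erosion_factor=truth.age_erosion[age])
        for rep in range(n_replicates):
            rng = np.random.default_rng(next(seeds))
            frames = []
            for contig, pos in truth.cpg_positions.items():
                depth = rng.poisson(lam, len(pos))
                keep = depth > 0
                meth = rng.binomial(depth[keep], expected[contig][keep])
                frames.append(pd.DataFrame({
                    "contig": contig, "pos": pos[keep] + 1, "strand": "+", "context": "CG",
                    "n_meth": meth, "n_total": depth[keep],
                }))
            records = pd.concat(frames, ignore_index=True)
            out[age].append(MethylomeTable(f"skim_{age}_rep{rep + 1}", records))
    return out
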