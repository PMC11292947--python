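# Methods

`mosaicmeth` analyses invertebrate-style *mosaic* DNA methylomes: genomes in
which 5-methylcytosine is confined largely to gene bodies at CpG
dinucleotides, against a lowly methylated background, with hypomethylated
promoters. The package takes per-cytosine methylation call tables (CGmap or
bisulfite-coverage dialect) plus gene models, TE/ATAC intervals, expression
matrices and orthologue tables, and produces global statistics, per-gene
gene-body methylation (GbM), differential/unmethylated region calls, TE
summaries and cross-species comparisons. Because the deposited sequencing
data behind such studies are too large for routine testing, the package
includes a first-class synthetic-methylome generator with a planted truth
table; every estimator is validated by recovering what the generator
planted.

## Estimators

**Global mCG.** The level of a sample is Σ methylated calls / Σ total calls
over CpGs with coverage strictly greater than a threshold (default 10×,
matching the common ">10× coverage" convention for deep libraries). Count
weighting is the default because pooled calls are what "global methylation
level" means operationally; an unweighted mean-of-fractions variant is
exposed for sensitivity analysis. CpG dyads are destranded on input (counts
of the minus-strand G are added to the plus-strand C) since every statistic
here is symmetric-CpG. With no passing CpG the estimate is returned
undefined rather than zero. Spike-in control contigs (`lambda_unmeth`,
`pUC19_meth`) are excluded from genome-wide statistics and instead feed
`nonconversion_rate`, which reports the apparent methylation of
known-unmethylated DNA (spike, mitochondrial, non-CpG contexts) as the
assay-error estimate.

**Genome skimming.** At very shallow coverage the same pooled-count
estimator is applied with no per-CpG filter; binomial thinning leaves its
expectation unchanged, which is why a few tens of thousands of pooled calls
suffice for a global level with a tight Wilson interval
(`aging_trajectory`).

**CpG observed/expected.** (#CpG × N) / (#C × #G) with an overlapping
dinucleotide scan, never across contig boundaries; non-ACGT bases are
excluded and break the scan. Values near 1 indicate no historical
germline-methylation depletion.

**Gene-body methylation.** A gene's GbM is the count-weighted mCG over all
CpGs in its full transcript span, introns included; exon-only and
intron-only modes exist for per-feature summaries. Genes with fewer than 5
covered CpGs or mean coverage below 4 are flagged and excluded downstream.
Methylation status uses GbM ≥ 20% by default; a strict (>) mode at 10%
serves treatment analyses. Decile ranking assigns near-equal groups with a
stable tie-break; values under an optional floor (TPM < 1) form a dedicated
non-expressed class.

**Twofold change rule.** For two stages, the mean GbM difference d̄ over all
genes passing filters in both captures the global drift; gene *g* is called
when |d_g − d̄| > 2|d̄| (deviation measured in units of the global change),
with the sign of d_g − d̄ giving direction. An alternative `abs2x` rule
(|d_g| > 2|d̄|) is exposed. If d̄ is exactly zero the rule degenerates and an
absolute-difference fallback is used, flagged in the output.

**DMR caller.** A deterministic substitute for shrinkage-based callers,
keeping their published parameters: at CpGs covered ≥ 4 in both samples,
the per-CpG difference is smoothed with a centred 3-CpG running mean (the
minimal smoothing that suppresses single-CpG noise seeds); seeds with
|smoothed difference| > 0.2 merge when same-direction and within 100 bp;
runs with ≥ 5 seeds and mean coverage ≥ 4 are reported with their raw mean
difference. The caller is antisymmetric under sample swap, calls nothing on
identical inputs, and — unlike its statistical counterparts — has no FDR
machinery: the effect-size threshold is the specificity control. A
consequence of centred smoothing is that a region's bounds typically
include one or two flanking CpGs, so boundary accuracy is CpG-scale (tens
of bp on average) rather than exact.

**Region annotation.** One category per region by precedence promoter >
exon > intron > distal-regulatory > intergenic. Two promoter conventions
coexist deliberately: (−1000, +200) around the TSS for DMR/distal-ATAC
annotation, and (−2000, +200) for UMR-promoter overlap; each call site
defaults to its own convention.

**UMR segmentation.** Maximal runs of consecutive covered CpGs with
fraction < 0.5, kept at ≥ 4 CpGs — an explicit run-definition substitute
for posterior-based segmenters, with their two published cutoffs as the
only parameters. Run segmentation at a 0.5 cutoff presumes the non-UMR
genome sits *above* the cutoff; on a mosaic ~30% methylome most individual
CpGs fall below 0.5, so UMRs tile much of the genome and only the
size-filtered (<5 kb strictly) promoter summary is informative. The
recovery validation therefore runs on a hypermethylated-background
configuration (background 0.78, bodies 0.65–0.9, promoters 0.02) where the
definition is sharp; this is stated here because it bounds what the test
shows about mosaic genomes.

**TE analyses.** TEs strictly longer than 400 bp are kept, classed genic on
any gene-span overlap, and scored for methylation like genes (≥ 20% =
methylated). Gene stratification counts introns containing a retained TE
and compares with-TE vs without-TE genes per intron-count bin with a
two-sided rank-sum test. Differential TE expression is a deterministic
pipeline: median-of-ratios size factors, log2(normalized+1), and a
moderated t in which per-TE pooled variances are shrunk toward the mean
variance of their average-abundance quantile bin with 20 prior degrees of
freedom, then Benjamini–Hochberg; calls need padj ≤ 0.01 and |log2FC| ≥ 2.
The moderation matters: an unmoderated t with two replicates per arm has ~2
degrees of freedom, cannot reach BH-significant p-values at realistic list
sizes, and is conservative at nominal size; the trended shrinkage gives
empirical type-I error ≈ 0.04 at α = 0.05 and full recovery of 8-fold
effects in simulation. Median-of-ratios assumes most TEs are unchanged;
contrasts where half the list is differential will defeat the
normalization, as they do for the tools this step substitutes for.

**Treatment comparison.** Per-replicate global levels, absolute and
relative depletion, and a pooled-variance two-sided unpaired t-test.
Pooled variance (not Welch) because replicated arms of the same design
share a variance and, at 2–3 replicates, Welch's random denominator df
makes the test noticeably conservative (~0.035 true size) while the pooled
test is exact under normality.

**Orthologue comparison.** Consumed one-to-one pairs are classified by the
20% threshold into methylated-both / unmethylated-both / hyper-in-either;
the classes partition the pairs and swap correctly under species exchange.
Expression comparisons quantile-normalize stages within species before
differencing (raw-TPM mode exposed); hyper-class shifts are tested against
the pooled symmetric classes with two-sided t-tests.

## The synthetic generator

`generate_genome` draws i.i.d. sequence at a set GC content (default 0.42,
so CpGs occur at ~4.4/100 bp), tiles non-overlapping multi-exon genes with
intergenic gaps, and places TEs half inside introns, half intergenically,
with lengths straddling the 400 bp filter; ATAC peaks cover half the
promoters plus distal sites. `make_truth` then fixes the generative truth:

- **Expression.** Per-gene mean TPM is log-normal (median ≈ 7, spanning
  ~3 orders of magnitude); the per-gene CV across stages is log-normal
  (median 0.5). The level and variability latents are correlated at −0.8 —
  highly expressed genes are transcriptionally stable. A configurable
  fraction (default 10%) of genes is non-expressed (mean TPM < 1). The
  stage matrix itself (default 8 stages) is drawn inside `make_truth`,
  because the methylation link below tracks the realized trajectory.
- **GbM link.** The target body methylation is linear in the rank of the
  gene's realized mean TPM (range 0.08–0.80) minus 0.45 × the centred rank
  of its realized CV, plus N(0, 0.04) noise; non-expressed genes sit at the
  bottom. The two links reinforce through the level–stability correlation,
  which is what makes both marginal decile patterns monotone. No effect
  sizes are established for these couplings in real annelids; these values
  are chosen so the planted pattern is strong enough to be recoverable at
  the simulated scale, and both links can be switched off.
- **Compartments.** Precedence planted DMR > promoter UMR > TE > gene body
  > intergenic background. Promoter windows (600 bp strictly upstream of
  the TSS, clipped at neighbouring gene bodies, ≥ 6 CpGs) are planted at
  0.02. TEs sit at 0.70 in "TE-methylating species" mode. The intergenic
  background defaults to the gene-body CpG-weighted mean divided by 1.15,
  planting the modest 1.1–1.2× body-over-background enrichment typical of
  mosaic methylomes; it can be overridden (e.g. 0.78 for the
  hypermethylated UMR-validation genome). Planted DMRs occupy CpG-dense
  intergenic windows (≥ 8 CpGs, inter-CpG gaps ≤ 80 bp) with between-stage
  contrast ≥ 0.2 by construction.
- **Stages and observation model.** Each stage multiplies all targets by an
  erosion factor (defaults 1.0 / 0.98 / 0.58 for gastrula / larva / adult,
  mirroring a life cycle whose adult methylome has lost ~40% of its
  embryonic level); factors must be non-increasing. Per-CpG totals are
  Poisson around the mean depth (zero-depth sites dropped); methylated
  counts are binomial around the apparent fraction p·(1−over-conversion) +
  non-conversion·(1−p), with non-conversion 0.01 and over-conversion 0.005.
  Spike-in contigs (fully unmethylated / fully methylated) and a thin
  sample of non-CpG cytosine records are appended so conversion controls
  are estimable. Treatment depletion thins methylated counts binomially
  (default fraction 0.042); skimming series use Poisson per-CpG depth with
  mean reads/n_CpGs across a strictly decreasing age-erosion ladder. All
  randomness descends from one seed through spawned generators.

What the generator does **not** emulate: read-level error profiles and
mapping bias, CpG-island sequence structure (CpGs are placed at random
density), correlated methylation noise between neighbouring CpGs beyond the
compartment structure, TE sequence families with real divergence, stage
effects in expression beyond i.i.d. draws, and biological replicate
variance beyond resampling. Passing recovery tests therefore demonstrates
estimator correctness under the declared stochastic model, not robustness
to alignment artefacts or covariate structure in real libraries.

## Validation scale and reproduction

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
all recovery metrics from scratch (`src/mosaicmeth/validation.py`): GbM
recovery on a 2 Mb / 1000-gene genome at 30× (truth correlation, MAE,
global error); decile monotonicity and link-off flatness at 1500 genes;
the metagene body/background ratio on a sparse-gene genome; DMR recovery
(60 planted, Δ = 0.35) plus null false positives per Mb; the twofold rule
(50 planted −0.2 shifts, drawn from genes with baseline GbM 0.35–0.7 so the
shift has headroom, among 1000 stable genes under −0.05 erosion); UMR
recovery (200 planted promoters); and statistical calibration (1000
null t-tests, 5 × 1000 null TEs, one planted 4.2% depletion). These problem
sizes keep the whole run under a minute while leaving every pass/fail
margin at several sigma. The `analysis/` scripts run the same estimators as
a narrative two-species study at a smaller scale (2 × 600 kb, 500 genes,
15×) and write their tables under `results/`.

## Known limitations

- The DMR caller's specificity comes from the effect-size threshold, not
  FDR control; very deep data with tiny systematic offsets (e.g. batchy
  conversion efficiency) would produce calls a shrinkage-based caller
  would suppress.
- UMR segmentation is only sharp on genomes whose background exceeds the
  0.5 cutoff (see above).
- `read_gene_models` keeps one transcript per gene (the longest), so
  GbM is per-gene, not per-isoform.
- The twofold rule is undefined in sign-free terms when the global drift is
  ~0; the fallback threshold is explicit but arbitrary (0.1).
- Cross-species trajectories require orthologue GbM in both species at the
  same stages; stages are matched by name only.
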