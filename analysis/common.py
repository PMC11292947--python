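"""Shared study configuration for the analysis scripts.

Two synthetic annelid-like species are simulated: species A has a mosaic
methylome with TE targeting and a strongly eroding life cycle (gastrula >
larva >> adult); species B lacks TE targeting and erodes more gently.  All
scripts derive their data from these two configurations and a single seed.
"""

import os

from mosaicmeth import synthetic as syn

SEED = 20260927
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

STAGES = ("gastrula", "larva", "adult")


def species_a(seed=SEED):
    seqs, ann, tes, atac = syn.generate_genome(
        n_contigs=2, contig_length=600_000, n_genes=500, n_tes=250, seed=seed,
        gene_length=(900, 2000), min_gap=600)
    truth = syn.make_truth(seqs, ann, tes, seed=seed + 1, stages=STAGES,
                           erosion=(1.0, 0.98, 0.58), te_mode=True)
    return seqs, ann, tes, atac, truth


def species_b(seed=SEED + 1000):
    seqs, ann, tes, atac = syn.generate_genome(
        n_contigs=2, contig_length=600_000, n_genes=500, n_tes=250, seed=seed,
        gene_length=(900, 2000), min_gap=600)
    truth = syn.make_truth(seqs, ann, tes, seed=seed + 1, stages=STAGES,
                           erosion=(1.0, 0.95, 0.82), te_mode=False)
    return seqs, ann, tes, atac, truth


def outdir():
    os.makedirs(RESULTS, exist_ok=True)
    return RESULTS
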