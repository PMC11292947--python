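"""Cross-species orthologue GbM comparison.

Pairs the two synthetic species' genes one-to-one, classifies pairs by the
20% GbM threshold, tracks per-stage cross-species correlations of GbM and
expression, and contrasts expression level/stability differences across the
hypermethylated classes.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import SEED, STAGES, outdir, species_a, species_b  # noqa: E402

from mosaicmeth import (class_vs_expression, classify_orthologue_pairs,  # noqa: E402
                        gene_body_methylation, interspecies_trajectories)
from mosaicmeth import synthetic as syn  # noqa: E402


def main():
    _, ann_a, _, _, truth_a = species_a()
    _, ann_b, _, _, truth_b = species_b()
    gbm_a, gbm_b = {}, {}
    for k, stage in enumerate(STAGES):
        ma = syn.generate_methylome(truth_a, stage, mean_depth=15, seed=SEED + 10 + k)
        mb = syn.generate_methylome(truth_b, stage, mean_depth=15, seed=SEED + 40 + k)
        gbm_a[stage] = gene_body_methylation(ma, ann_a)
        gbm_b[stage] = gene_body_methylation(mb, ann_b)
    # relabel species B genes so the two id spaces are distinct, as real
    # orthology tables are
    for stage in STAGES:
        gbm_b[stage].index = ["B_" + g for g in gbm_b[stage].index]
    pairs = pd.DataFrame({"gene1": list(gbm_a[STAGES[0]].index),
                          "gene2": list(gbm_b[STAGES[0]].index)})

    comp = classify_orthologue_pairs(gbm_a["adult"], gbm_b["adult"], pairs)
    comp.to_csv(os.path.join(outdir(), "orthologue_classes.tsv"), sep="\t", index=False)
    print(f"Classified pairs: {len(comp)} ({comp.attrs['n_excluded']} excluded by filters)")
    print(pd.Series(comp.attrs["class_fractions"]).round(3).to_string())

    expr_a = syn.generate_expression(truth_a)
    expr_b = syn.generate_expression(truth_b)
    expr_b.index = ["B_" + g for g in expr_b.index]
    traj = interspecies_trajectories(gbm_a, gbm_b, expr_a, expr_b, pairs)
    traj.to_csv(os.path.join(outdir(), "interspecies_trajectories.tsv"), sep="\t")
    print("\nPer-stage cross-species rank correlations "
          "(the species are generated independently, so both hover near zero):")
    print(traj.to_string())

    cls = class_vs_expression(comp, expr_a, expr_b)
    cls.to_csv(os.path.join(outdir(), "class_vs_expression.tsv"), sep="\t")
    print("\nPer-class species differences in log2 expression and CV:")
    print(cls[["n", "mean_d_log_expr", "mean_d_cv", "p_expr"]].to_string())


if __name__ == "__main__":
    main()
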