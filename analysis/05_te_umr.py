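"""Transposable-element methylation/expression and unmethylated regions.

Scores TE methylation by genomic location in the TE-methylating species,
stratifies gene-body methylation by intronic TE content, runs the
simplified TE differential-expression test on a treatment-style contrast
with mostly intergenic planted reactivation, and segments UMRs.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import SEED, outdir, species_a  # noqa: E402

from mosaicmeth import (call_umrs, filter_and_classify_tes,  # noqa: E402
                        gbm_by_intron_te_strata, gene_body_methylation,
                        promoter_umr_summary, te_differential_expression)
from mosaicmeth import synthetic as syn  # noqa: E402


def main():
    seqs, ann, tes, _, truth = species_a()
    meth = syn.generate_methylome(truth, "gastrula", mean_depth=15, seed=SEED + 10)

    te_table = filter_and_classify_tes(tes, ann, meth)
    te_table.to_csv(os.path.join(outdir(), "te_methylation.tsv"), sep="\t", index=False)
    summary = te_table.groupby("location")["status"].value_counts().unstack(fill_value=0)
    print(f"TEs retained after the >400 bp filter: {len(te_table)}")
    print(summary.to_string())

    gbm = gene_body_methylation(meth, ann)
    strata, comp = gbm_by_intron_te_strata(gbm, ann, tes)
    comp.to_csv(os.path.join(outdir(), "gbm_intron_te_strata.tsv"), sep="\t", index=False)
    print("\nGbM, genes with vs without intronic TEs (per intron-count bin):")
    print(comp.to_string(index=False))

    # TE reactivation contrast: 10% of TEs upregulated 8-fold, 85% intergenic
    rng = np.random.default_rng(SEED + 5)
    labels = list(te_table["label"])
    inter = [t for t in labels if te_table.set_index("label").loc[t, "location"] == "intergenic"]
    genic = [t for t in labels if t not in set(inter)]
    n_up = max(1, len(labels) // 10)
    n_inter = int(round(0.85 * n_up))
    up = (list(rng.choice(inter, min(n_inter, len(inter)), replace=False))
          + list(rng.choice(genic, min(n_up - n_inter, len(genic)), replace=False)))
    mu = pd.Series(rng.lognormal(4, 1, len(labels)), index=labels)
    mu_t = mu.copy()
    mu_t[up] *= 8
    counts = pd.DataFrame({"c1": rng.poisson(mu), "c2": rng.poisson(mu),
                           "z1": rng.poisson(mu_t), "z2": rng.poisson(mu_t)},
                          index=labels)
    res = te_differential_expression(counts, {"c1": "c", "c2": "c", "z1": "z", "z2": "z"},
                                     te_table=te_table)
    res.to_csv(os.path.join(outdir(), "te_differential_expression.tsv"), sep="\t")
    ct = res.attrs["location_crosstab"]
    print(f"\nTE DE: {int((res['call'] == 'up').sum())} up-called of {len(up)} planted")
    if "up" in getattr(ct, "index", []):
        share = ct.loc["up", "intergenic"] / ct.loc["up"].sum()
        print(f"intergenic share of upregulated TEs: {100 * share:.1f}%")

    umrs = call_umrs(meth)
    summ = promoter_umr_summary(umrs, ann)
    pd.DataFrame([{"n_umrs": summ["n_umrs"],
                   "n_excluded_by_size": summ["n_excluded_by_size"],
                   "promoter_fraction": summ["promoter_fraction"]}]).to_csv(
        os.path.join(outdir(), "umr_summary.tsv"), sep="\t", index=False)
    print(f"\nUMRs (<5 kb): {summ['n_umrs']}, promoter-overlap fraction "
          f"{summ['promoter_fraction']:.2f} (on a mosaic ~30% methylome the 0.5 "
          f"cutoff segments most of the genome as low; see docs/methods.md)")


if __name__ == "__main__":
    main()
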