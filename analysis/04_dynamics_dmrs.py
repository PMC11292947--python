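"""Between-stage dynamics: twofold GbM changes, DMRs, treatment depletion.

Calls genes whose gastrula-to-adult GbM change deviates twofold from the
global erosion, segments DMRs between the two stages and annotates them
against genes / ATAC peaks / TEs, and quantifies a simulated
cytidine-analog treatment that strips 4.2% of methylated calls genome-wide.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import SEED, outdir, species_a  # noqa: E402

from mosaicmeth import (annotate_regions, call_dmrs, compare_depletion,  # noqa: E402
                        detect_gbm_changes, gene_body_methylation)
from mosaicmeth import synthetic as syn  # noqa: E402


def main():
    seqs, ann, tes, atac, truth = species_a()
    m_gast = syn.generate_methylome(truth, "gastrula", mean_depth=15, seed=SEED + 10)
    m_adult = syn.generate_methylome(truth, "adult", mean_depth=15, seed=SEED + 12)

    g_gast = gene_body_methylation(m_gast, ann)
    g_adult = gene_body_methylation(m_adult, ann)
    changes = detect_gbm_changes(g_gast, g_adult)
    counts = changes["call"].value_counts()
    changes.to_csv(os.path.join(outdir(), "gbm_changes_gastrula_adult.tsv"), sep="\t")
    print(f"Twofold rule (gastrula->adult), global mean difference "
          f"{changes['global_mean_difference'].iloc[0]:.3f}:")
    print(counts.to_string())

    dmrs = call_dmrs(m_gast, m_adult)
    annotated = annotate_regions(dmrs, ann, atac, tes)
    annotated.to_csv(os.path.join(outdir(), "dmrs_annotated.tsv"), sep="\t", index=False)
    print(f"\n{len(dmrs)} DMRs between gastrula and adult "
          f"(multiplicative erosion scales methylated regions most);")
    if len(annotated):
        print(annotated["category"].value_counts().to_string())

    # treatment emulation: stochastic loss of 4.2% of methylated calls
    ctrl = [syn.generate_methylome(truth, "larva", 8, seed=SEED + 100 + i,
                                   include_spikes=False, include_non_cg=False)
            for i in range(3)]
    treated = [syn.apply_global_depletion(
        syn.generate_methylome(truth, "larva", 8, seed=SEED + 200 + i,
                               include_spikes=False, include_non_cg=False),
        truth.depletion_fraction, seed=SEED + 300 + i) for i in range(3)]
    res = compare_depletion(ctrl, treated)
    pd.DataFrame([{k: v for k, v in res.items()
                   if k not in ("control_levels", "treated_levels")}]).to_csv(
        os.path.join(outdir(), "depletion_comparison.tsv"), sep="\t", index=False)
    print(f"\nTreatment arm: relative depletion {100 * res['relative_depletion']:.2f}% "
          f"(planted {100 * truth.depletion_fraction}%), two-sided t-test p = {res['p']:.2g}")


if __name__ == "__main__":
    main()
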