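import pandas as pd
import pytest

from mosaicmeth import synthetic as syn
from mosaicmeth.io_formats import METH_COLUMNS, GenomeAnnotation, MethylomeTable


@pytest.fixture(scope="session")
def small_world():
    """A small deep-coverage synthetic dataset shared across tests."""
    seqs, ann, tes, atac = syn.generate_genome(
        n_contigs=2, contig_length=150_000, n_genes=60, n_tes=30, seed=11,
        gene_length=(800, 1600), min_gap=600)
    truth = syn.make_truth(seqs, ann, tes, seed=11)
    meth = syn.generate_methylome(truth, "gastrula", mean_depth=30, seed=12)
    return {"sequences": seqs, "annotation": ann, "tes": tes, "atac": atac,
            "truth": truth, "methylome": meth}


def make_methylome(rows, sample_id="test"):
    """Construct a MethylomeTable from (contig, pos, strand, context, m, t) rows."""
    return MethylomeTable(sample_id, pd.DataFrame(rows, columns=METH_COLUMNS))


def make_annotation(genes, exons=None, contig_lengths=None):
    """Construct a GenomeAnnotation from (gene_id, contig, strand, start, end) rows."""
    df = pd.DataFrame(genes, columns=["gene_id", "contig", "strand", "start", "end"]
                      ).set_index("gene_id")
    if exons is None:
        exons = {gid: [(int(g["start"]), int(g["end"]))] for gid, g in df.iterrows()}
    return GenomeAnnotation(df, exons, contig_lengths or {})
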