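import numpy as np
import pytest

from binscreen.annotation import annotate_bins, derive_all_features
from binscreen.binning import dedup_insertions, tally
from binscreen.models import GeneModel, GenomeLayout, Insertion


@pytest.fixture
def toy_gene():
    """Two-exon coding gene on '+': tx [3000, 9000), cds [3500, 8500)."""
    return GeneModel(
        gene_name="geneA",
        chrom="chr1",
        strand="+",
        tx_start=3000,
        tx_end=9000,
        cds_start=3500,
        cds_end=8500,
        exon_starts=(3000, 6000),
        exon_ends=(4000, 9000),
    )


@pytest.fixture
def toy_layout():
    return GenomeLayout(chrom_sizes={"chr1": 20_000}, bin_length=250)


def make_table(genes, insertions, layout, promoter_length=2000):
    """Small-fixture pipeline: features -> bin annotation -> tallied table."""
    features = derive_all_features(list(genes), layout, promoter_length)
    annotation = annotate_bins(features, layout)
    return tally(dedup_insertions(list(insertions)), annotation, layout)


def spread_insertions(layout, population, n, strand="+", seed=0):
    """n background insertions at distinct positions across the genome."""
    rng = np.random.default_rng(seed)
    chrom = next(iter(layout.chrom_sizes))
    size = layout.chrom_sizes[chrom]
    positions = rng.choice(size, size=n, replace=False)
    return [Insertion(chrom, int(p), strand, population) for p in positions]
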