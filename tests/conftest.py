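import numpy as np
import pytest

from aberex.annotation import CanonicalExon, GeneModel, GenomicInterval


def make_exon(chrom, start, end, strand, gene_id, idx, biotype="protein_coding"):
    return CanonicalExon(
        interval=GenomicInterval(chrom, start, end, strand),
        exon_id=f"{gene_id}.E{idx}",
        gene_id=gene_id,
        gene_name=gene_id.lower(),
        biotype=biotype,
        transcript_ids={f"{gene_id}.t1"},
    )


def make_gene(gene_id, chrom, strand, exon_coords, biotype="protein_coding"):
    exons = [
        make_exon(chrom, s, e, strand, gene_id, i + 1, biotype)
        for i, (s, e) in enumerate(exon_coords)
    ]
    return GeneModel(gene_id, gene_id.lower(), biotype, strand, exons)


@pytest.fixture
def toy_genes():
    """Three genes: two plus-strand (one with close exons), one minus-strand."""
    return [
        make_gene("GA", "chr1", "+", [(1000, 1200), (2000, 2150), (3000, 3300)]),
        make_gene("GB", "chr1", "-", [(5000, 5180), (6000, 6220), (7000, 7100)]),
        make_gene("GC", "chr2", "+", [(100, 250), (800, 950)]),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
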