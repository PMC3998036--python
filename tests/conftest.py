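import pytest

from splicetk.model import GeneModel, GenomicInterval, TranscriptModel
from splicetk.reference import MOST_EXPRESSED, PRE_RNA, ReferenceModel


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def tx(tid, exon_pairs, strand="+", gene_id="G1", chrom="chr1"):
    return TranscriptModel(
        tid, gene_id, chrom, strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs),
    )


@pytest.fixture
def toy_reference():
    """Four-exon reference E1=[100,200) E2=[300,400) E3=[500,600)
    E4=[700,800) on the plus strand."""
    return ReferenceModel(
        gene_id="G1",
        mode=MOST_EXPRESSED,
        chrom="chr1",
        strand="+",
        merged_exons=(iv(100, 200), iv(300, 400), iv(500, 600), iv(700, 800)),
        source_transcript_id="Tref",
    )


def make_gene(transcripts, gene_id="G1"):
    return GeneModel(gene_id, tuple(transcripts))


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderately sized generated dataset shared across tests."""
    from splicetk.simulate import generate_dataset

    return generate_dataset(40, seed=20240901)
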