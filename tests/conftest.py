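import pytest

from circsieve.annotation import GeneModel, build_boundary_index


@pytest.fixture
def three_exon_model():
    """One '+' transcript with exons [100,200), [300,400), [500,600)."""
    return GeneModel(
        gene_name="GENE1",
        transcript_id="TX0001",
        chrom="chr1",
        strand="+",
        exon_starts=(100, 300, 500),
        exon_ends=(200, 400, 600),
    )


@pytest.fixture
def minus_model():
    """One '-' transcript with exons [1000,1100), [1300,1400)."""
    return GeneModel(
        gene_name="GENE2",
        transcript_id="TX0002",
        chrom="chr1",
        strand="-",
        exon_starts=(1000, 1300),
        exon_ends=(1100, 1400),
    )


@pytest.fixture
def index(three_exon_model, minus_model):
    return build_boundary_index([three_exon_model, minus_model])
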