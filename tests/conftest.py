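import pytest

from phagecomp.genome_model import GeneFeature, GenomeRecord, OrthologTable


@pytest.fixture
def toy_genome():
    # 60 bp: two CDS on + and -, one tRNA, gaps in between
    seq = "ATGAAATAGCCCCCCCCCCTTACATTTTCATGGGGGGGGGGACGTACGTACGTACGTACG"
    return GenomeRecord(genome_id="g1", sequence=seq)


@pytest.fixture
def toy_features():
    return [
        GeneFeature("cds1", "g1", 0, 9, "+", "CDS", product="protA"),
        GeneFeature("cds2", "g1", 19, 31, "-", "CDS", product="protB"),
        GeneFeature("trna1", "g1", 41, 50, "+", "tRNA", product="tRNA-Leu(UAA)"),
    ]


@pytest.fixture
def toy_table():
    return OrthologTable(
        [("cds1", "g1", "ogA"), ("cds2", "g1", "ogB")]
    )
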