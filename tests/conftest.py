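import numpy as np
import pytest

from fusionskew.coverage import ExonCoverageProfile
from fusionskew.fusion_evidence import Breakpoint, FusionRecord
from fusionskew.genemodel import GeneModel
from fusionskew.synthetic_data import GeneSpec, make_toy_gtf


def make_profile(counts, lengths=None, gene_id="G1", sample_id="S1"):
    counts = np.asarray(counts, dtype=float)
    if lengths is None:
        lengths = np.ones_like(counts)
    return ExonCoverageProfile(
        gene_id=gene_id, sample_id=sample_id, counts=counts, lengths=lengths
    )


def make_record(
    gene5="AAA",
    gene3="BBB",
    bp5=("chr1", 1000, "+"),
    bp3=("chr1", 5000, "+"),
    jrc=5,
    sfc=5,
    **kwargs,
):
    return FusionRecord(
        fusion_name=f"{gene5}--{gene3}",
        gene5=gene5,
        gene3=gene3,
        breakpoint5=Breakpoint(*bp5),
        breakpoint3=Breakpoint(*bp3),
        junction_read_count=jrc,
        spanning_frag_count=sfc,
        **kwargs,
    )


@pytest.fixture
def toy_gtf(tmp_path):
    """Two-transcript plus-strand gene, two-exon minus-strand gene, a lincRNA."""
    text = make_toy_gtf(
        [
            GeneSpec(
                gene_id="GPLUS",
                chrom="chr1",
                strand="+",
                transcripts=[[(100, 200)], [(150, 300)]],
            ),
            GeneSpec(
                gene_id="GMINUS",
                chrom="chr1",
                strand="-",
                transcripts=[[(1000, 1100), (1200, 1300)]],
            ),
            GeneSpec(
                gene_id="GLINC",
                chrom="chr2",
                strand="+",
                biotype="lincRNA",
                transcripts=[[(500, 900)]],
            ),
        ]
    )
    path = tmp_path / "toy.gtf"
    path.write_text(text)
    return path


@pytest.fixture
def simple_gene_model():
    from fusionskew.genemodel import Exon

    return GeneModel(
        gene_id="G1",
        symbol="G1",
        chrom="chr1",
        strand="+",
        biotype="protein_coding",
        exons=[Exon("chr1", 100, 200, 1), Exon("chr1", 300, 450, 2)],
    )
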