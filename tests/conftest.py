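"""Shared fixtures: a hand-built toy gene on each strand and a generated bundle.

The plus-strand toy gene has one exon at 101-160 with CDS 111-140 whose
spliced sequence is ATGGCTGAATTCGGACATAAACCCGTATGA -> protein MAEFGHKPV
(9 aa, hand-translated with the standard genetic code).  The minus-strand
twin carries the identical coding sequence reverse-complemented into the
genome, so every protein-level assertion must hold unchanged.
"""

from __future__ import annotations

import pytest

from varlollipop.fixtures import FixtureSpec, generate_bundle
from varlollipop.gene_model import GeneModel, Genome, Transcript, attach_translation

TOY_CDS = "ATGGCTGAATTCGGACATAAACCCGTATGA"
TOY_PROTEIN = "MAEFGHKPV"

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def build_plus_toy() -> tuple[GeneModel, Genome]:
    """Single-exon plus-strand gene: exon 101-160, CDS 111-140."""
    utr5 = "GTACGTACGT"  # 101-110
    utr3 = "ACGTACGTACGTACGTACGT"  # 141-160
    seq = "A" * 100 + utr5 + TOY_CDS + utr3 + "C" * 40
    genome = Genome({"chrT": seq})
    tr = Transcript(
        transcript_id="T1",
        biotype="protein_coding",
        chrom="chrT",
        strand="+",
        exons=[(101, 160)],
        cds_segments=[(111, 140)],
    )
    attach_translation(tr, genome)
    gene = GeneModel(
        gene_id="G1", symbol="TOYP", chrom="chrT", strand="+",
        span=(101, 160), transcripts=[tr],
    )
    return gene, genome


def build_minus_toy() -> tuple[GeneModel, Genome]:
    """Same coding sequence on the minus strand: exon 101-160, CDS 121-150."""
    utr3 = "ACGTACGTACGTACGTACGT"  # 101-120 (3' in transcription order)
    utr5 = "GTACGTACGT"  # 151-160
    seq = "A" * 100 + utr3 + revcomp(TOY_CDS) + utr5 + "C" * 40
    genome = Genome({"chrT": seq})
    tr = Transcript(
        transcript_id="T1m",
        biotype="protein_coding",
        chrom="chrT",
        strand="-",
        exons=[(101, 160)],
        cds_segments=[(121, 150)],
    )
    attach_translation(tr, genome)
    gene = GeneModel(
        gene_id="G1M", symbol="TOYM", chrom="chrT", strand="-",
        span=(101, 160), transcripts=[tr],
    )
    return gene, genome


@pytest.fixture(scope="session")
def plus_toy():
    return build_plus_toy()


@pytest.fixture(scope="session")
def minus_toy():
    return build_minus_toy()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The seed-1 fixture bundle shared across the suite (read-only)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(FixtureSpec(seed=1), str(out))


MINIMAL_VCF = """##fileformat=VCFv4.2
##reference=file:///data/GRCh38.fa
##contig=<ID=chrT,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
chrT\t117\t.\tG\tT\t.\tPASS\t.\tGT\t0/1
"""


@pytest.fixture
def minimal_vcf() -> str:
    return MINIMAL_VCF
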