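"""Gene/transcript models, genome access, and the per-chromosome interval index.

Gene models come from Ensembl-flavoured GFF3 (gene -> mRNA -> exon/CDS via
``Parent`` links, parsed with :mod:`gffutils`) and the genome from FASTA.
Every protein-coding transcript's spliced CDS is read 5'->3' (reverse
complemented on the minus strand) and translated with the standard genetic
code; transcripts whose CDS does not start with ATG, does not end with a
stop, is not a multiple of three, or contains an internal stop are flagged
non-translatable and excluded from protein-level plotting.

All public coordinates are 1-based inclusive, as in GFF3 and VCF.  The
interval index stores half-open 0-based intervals internally
(:mod:`intervaltree` convention) but never exposes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .vcf_io import VariantRecord

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


class GeneModelError(Exception):
    pass


class Genome:
    """In-memory genome with 1-based inclusive ``fetch``."""

    def __init__(self, sequences: dict[str, str]):
        self._seq = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, fasta: str | IO) -> "Genome":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(fasta, "fasta")})

    @property
    def contig_names(self) -> set[str]:
        return set(self._seq)

    def contig_length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of chrom[start..end], 1-based inclusive."""
        if chrom not in self._seq:
            raise GeneModelError(f"contig {chrom!r} not in genome")
        if start < 1 or end > len(self._seq[chrom]):
            raise GeneModelError(
                f"{chrom}:{start}-{end} outside contig (len {len(self._seq[chrom])})"
            )
        return self._seq[chrom][start - 1 : end]


@dataclass
class Transcript:
    transcript_id: str
    biotype: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # genomic order, 1-based inclusive, disjoint
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    canonical_flag: bool = False
    cds_sequence: str | None = None  # spliced, translation order
    protein_sequence: str | None = None  # stop excluded
    translatable: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise GeneModelError(
                    f"{self.transcript_id}: overlapping exons near {s1}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def protein_length(self) -> int | None:
        return len(self.protein_sequence) if self.protein_sequence else None

    def cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in translation (5'->3') order."""
        pos = [p for s, e in self.cds_segments for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]


@dataclass
class ProteinFeature:
    label: str
    category: str  # "domain" | "feature"
    aa_start: int
    aa_end: int
    source: str = ""
    transcript_id: str = ""


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: list[Transcript] = field(default_factory=list)

    def coding_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.translatable]


def spliced_cds(transcript: Transcript, genome: Genome) -> str:
    """Spliced CDS in translation order (reverse-complemented on minus)."""
    parts = [genome.fetch(transcript.chrom, s, e) for s, e in transcript.cds_segments]
    seq = "".join(parts)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def attach_translation(transcript: Transcript, genome: Genome) -> None:
    """Translate the CDS and set the translatable flag.

    A fatal error is raised when the CDS extends beyond its contig; biological
    defects (no ATG, internal stop, length not divisible by 3) only flag the
    transcript non-translatable.
    """
    if not transcript.is_coding:
        transcript.translatable = False
        return
    last = transcript.cds_segments[-1][1]
    if last > genome.contig_length(transcript.chrom):
        raise GeneModelError(
            f"{transcript.transcript_id}: CDS extends beyond contig {transcript.chrom}"
        )
    cds = spliced_cds(transcript, genome)
    transcript.cds_sequence = cds
    if len(cds) % 3 != 0 or not cds.startswith(START_CODON):
        transcript.translatable = False
        return
    if cds[-3:] not in STOP_CODONS:
        transcript.translatable = False
        return
    protein = str(Seq(cds).translate())
    if "*" in protein[:-1] or not protein.endswith("*"):
        transcript.translatable = False
        return
    transcript.protein_sequence = protein[:-1]
    transcript.translatable = True


def load_gene_models(
    gff3: str, fasta: str | IO
) -> tuple[list[GeneModel], Genome]:
    """Load gene models from GFF3 + genome FASTA.

    *gff3* may be a file path or the GFF3 text itself.  Orphan exons/CDS
    (no resolvable mRNA parent) are skipped with a warning.
    """
    genome = Genome.from_fasta(fasta)
    from_string = isinstance(gff3, str) and "\t" in gff3
    db = gffutils.create_db(
        gff3,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        symbol = g.attributes.get("Name", [g.id])[0]
        gene = GeneModel(
            gene_id=g.id,
            symbol=symbol,
            chrom=g.seqid,
            strand=g.strand,
            span=(g.start, g.end),
        )
        for t in db.children(g, featuretype=("mRNA", "transcript"), level=1):
            biotype = t.attributes.get("biotype", ["protein_coding"])[0]
            tags = t.attributes.get("tag", []) + t.attributes.get(
                "Ensembl_canonical", []
            )
            canonical = any("canonical" in tag.lower() or tag == "1" for tag in tags)
            exons = [
                (e.start, e.end) for e in db.children(t, featuretype="exon", level=1)
            ]
            cds = [
                (c.start, c.end) for c in db.children(t, featuretype="CDS", level=1)
            ]
            if not exons:
                logger.warning("transcript %s has no exons; skipped", t.id)
                continue
            tr = Transcript(
                transcript_id=t.id,
                biotype=biotype,
                chrom=g.seqid,
                strand=t.strand,
                exons=exons,
                cds_segments=cds,
                canonical_flag=canonical,
            )
            attach_translation(tr, genome)
            gene.transcripts.append(tr)
        if gene.transcripts:
            lo = min(t.span[0] for t in gene.transcripts)
            hi = max(t.span[1] for t in gene.transcripts)
            gene.span = (min(gene.span[0], lo), max(gene.span[1], hi))
            genes.append(gene)
        else:
            logger.warning("gene %s has no usable transcripts; skipped", g.id)
    return genes, genome


def load_protein_features(tsv: str | IO) -> list[ProteinFeature]:
    """Sidecar TSV of protein domains/features.

    Columns: transcript_id, label, category, aa_start, aa_end, source.
    """
    import pandas as pd

    df = pd.read_csv(tsv, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProteinFeature(
                transcript_id=row.transcript_id,
                label=row.label,
                category=row.category,
                aa_start=int(row.aa_start),
                aa_end=int(row.aa_end),
                source=getattr(row, "source", ""),
            )
        )
    return out


def select_canonical(gene: GeneModel) -> Transcript:
    """The transcript to draw: flagged canonical, else longest CDS, ties by id."""
    coding = gene.coding_transcripts()
    if not coding:
        raise GeneModelError(f"no plottable transcript for gene {gene.symbol}")
    flagged = [t for t in coding if t.canonical_flag]
    if len(flagged) == 1:
        return flagged[0]
    return min(coding, key=lambda t: (-t.cds_length, t.transcript_id))


class GeneIndex:
    """Per-chromosome interval tree over gene spans."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._genes: dict[str, GeneModel] = {}

    @classmethod
    def build(cls, genes: Iterable[GeneModel]) -> "GeneIndex":
        idx = cls()
        for gene in genes:
            tree = idx._trees.setdefault(gene.chrom, IntervalTree())
            s, e = gene.span
            tree.addi(s - 1, e, gene.gene_id)  # half-open 0-based inside only
            idx._genes[gene.gene_id] = gene
        return idx

    def gene(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def by_symbol(self, symbol: str) -> GeneModel | None:
        for g in self._genes.values():
            if g.symbol == symbol:
                return g
        return None

    def symbols(self) -> list[str]:
        return sorted(g.symbol for g in self._genes.values())

    def query(self, chrom: str, pos: int) -> set[str]:
        """Gene ids whose span contains the 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos - 1)}


def build_index(genes: Iterable[GeneModel]) -> GeneIndex:
    return GeneIndex.build(genes)


@dataclass
class GeneHit:
    gene_id: str
    symbol: str
    variant_count: int
    carrier_sample_count: int


def genes_with_variants(
    index: GeneIndex, records: Sequence[VariantRecord]
) -> list[GeneHit]:
    """Genes hit by >=1 record, with distinct-variant and carrier-sample counts.

    A record overlapping two genes counts in both; the list is sorted by
    gene symbol.
    """
    per_gene_variants: dict[str, set[tuple]] = {}
    per_gene_carriers: dict[str, set[str]] = {}
    for rec in records:
        for gid in index.query(rec.chrom, rec.pos):
            per_gene_variants.setdefault(gid, set()).add(rec.key)
            carriers = per_gene_carriers.setdefault(gid, set())
            carriers.update(g.sample_id for g in rec.carrier_genotypes())
    hits = [
        GeneHit(
            gene_id=gid,
            symbol=index.gene(gid).symbol,
            variant_count=len(keys),
            carrier_sample_count=len(per_gene_carriers.get(gid, set())),
        )
        for gid, keys in per_gene_variants.items()
    ]
    return sorted(hits, key=lambda h: h.symbol)
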