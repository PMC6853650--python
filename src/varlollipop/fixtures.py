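"""Deterministic generator of toy genomes, gene models, annotation tables
and multi-sample VCFs.

Every stage of the pipeline can be exercised offline at desk scale: the
generator invents a small contig, plants protein-coding genes on both
strands (spliced CDS guaranteed to start with ATG, end with a stop and
contain no internal stop — enforced by construction, codons drawn from the
non-stop set), then plants variants in chosen region classes (coding SNVs
and indels, UTRs, introns, splice dinucleotides) with random multi-sample
genotypes, and covers a configurable fraction of them in each annotation
table so that absence paths are always exercised.

The ground truth for every planted variant — its region and its expected
consequence, computed with the brute-force rebuild-and-translate oracle at
generation time, never with the consequence engine — is written to a sidecar
TSV, which is what end-to-end tests compare the pipeline against.

Everything is driven by one ``random.Random(seed)``: the same spec yields a
byte-identical bundle.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

from . import oracle
from .gene_model import GeneModel, Genome, Transcript, attach_translation

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)
COMPLEMENT = str.maketrans("ACGT", "TGCA")

CLINVAR_CLASSES = (
    "Pathogenic",
    "Likely_pathogenic",
    "Uncertain_significance",
    "Likely_benign",
    "Benign",
)


class FixtureError(Exception):
    pass


@dataclass
class FixtureSpec:
    seed: int = 1
    n_genes: int = 2
    n_samples: int = 5
    n_variants_per_gene: int = 10
    exons_per_transcript: tuple[int, int] = (2, 3)
    cds_codons: tuple[int, int] = (40, 70)  # includes start and stop codons
    utr_length: tuple[int, int] = (6, 15)
    intron_length: tuple[int, int] = (30, 80)
    contig: str = "chrT"
    intergenic_gap: int = 200
    indel_fraction: float = 0.15  # of coding variants
    region_fractions: dict = field(
        default_factory=lambda: {"cds": 0.6, "utr": 0.15, "intron": 0.15, "splice": 0.1}
    )
    annotation_coverage: dict = field(
        default_factory=lambda: {
            "gnomad": 0.6,
            "dbsnp": 0.5,
            "clinvar": 0.35,
            "cosmic": 0.25,
            "scores": 0.5,
        }
    )
    max_total_exonic: int | None = None  # exon budget; None = unconstrained

    def validate(self) -> None:
        if self.cds_codons[0] < 3:
            raise FixtureError("cds_codons must allow start + >=1 aa + stop")
        if self.exons_per_transcript[0] < 1:
            raise FixtureError("need at least one exon per transcript")
        if abs(sum(self.region_fractions.values()) - 1.0) > 1e-6:
            raise FixtureError("region_fractions must sum to 1")
        if self.max_total_exonic is not None:
            need = 3 * self.cds_codons[0] + 2 * self.utr_length[0]
            if need > self.max_total_exonic:
                raise FixtureError(
                    f"CDS of >= {need} nt cannot fit exon budget {self.max_total_exonic}"
                )


@dataclass
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    transcript_id: str
    region: str
    expected_consequence: str
    genotypes: list[str] = field(default_factory=list)  # GT strings, sample order


@dataclass
class Bundle:
    """Paths of a generated fixture bundle plus its in-memory models."""

    directory: str
    fasta: str
    gff3: str
    vcf: str
    domains_tsv: str
    annotation_dir: str
    truth_tsv: str
    genes: list[GeneModel]
    genome: Genome
    planted: list[PlantedVariant]
    sample_names: list[str]


def _design_gene(
    rng: random.Random, idx: int, spec: FixtureSpec, start: int
) -> tuple[GeneModel, dict[int, str]]:
    """Lay out one gene from *start*; returns the model and pos->base writes."""
    strand = "+" if idx % 2 == 0 else "-"
    codons = rng.randint(*spec.cds_codons)
    L = 3 * codons
    u = rng.randint(*spec.utr_length)
    d = rng.randint(*spec.utr_length)
    total_exonic = u + L + d
    if spec.max_total_exonic is not None and total_exonic > spec.max_total_exonic:
        raise FixtureError(
            f"gene {idx}: exonic length {total_exonic} exceeds budget "
            f"{spec.max_total_exonic}"
        )
    n_exons = rng.randint(*spec.exons_per_transcript)
    # random composition of total_exonic into n_exons parts, each >= 8
    lengths: list[int] = []
    remaining = total_exonic
    for i in range(n_exons - 1):
        hi = remaining - 8 * (n_exons - 1 - i)
        ln = rng.randint(8, max(8, hi))
        lengths.append(ln)
        remaining -= ln
    lengths.append(remaining)
    exons: list[tuple[int, int]] = []
    cursor = start
    for i, ln in enumerate(lengths):
        exons.append((cursor, cursor + ln - 1))
        cursor = cursor + ln + (rng.randint(*spec.intron_length) if i < n_exons - 1 else 0)

    # transcription-order mapping of spliced index -> genomic position
    if strand == "+":
        spliced = [p for s, e in exons for p in range(s, e + 1)]
    else:
        spliced = [p for s, e in reversed(exons) for p in range(e, s - 1, -1)]
    coding = (
        "ATG"
        + "".join(rng.choice(NON_STOP_CODONS) for _ in range(codons - 2))
        + rng.choice(STOP_CODONS)
    )
    writes: dict[int, str] = {}
    cds_genomic: list[int] = []
    for i, base in enumerate(coding):
        p = spliced[u + i]
        writes[p] = base if strand == "+" else base.translate(COMPLEMENT)
        cds_genomic.append(p)
    # CDS segments = runs of consecutive genomic positions
    cds_sorted = sorted(cds_genomic)
    segments: list[tuple[int, int]] = []
    seg_start = prev = cds_sorted[0]
    for p in cds_sorted[1:]:
        if p != prev + 1:
            segments.append((seg_start, prev))
            seg_start = p
        prev = p
    segments.append((seg_start, prev))

    gene_id = f"G{idx + 1:03d}"
    transcript = Transcript(
        transcript_id=f"{gene_id}.t1",
        biotype="protein_coding",
        chrom=spec.contig,
        strand=strand,
        exons=exons,
        cds_segments=segments,
        canonical_flag=True,
    )
    gene = GeneModel(
        gene_id=gene_id,
        symbol=f"TOY{idx + 1}",
        chrom=spec.contig,
        strand=strand,
        span=(exons[0][0], exons[-1][1]),
        transcripts=[transcript],
    )
    return gene, writes


def _plant_variants(
    rng: random.Random,
    gene: GeneModel,
    genome: Genome,
    spec: FixtureSpec,
) -> list[PlantedVariant]:
    tr = gene.transcripts[0]
    rmap = oracle.region_map(tr)
    pools = {
        "cds": sorted(p for p, r in rmap.items() if r == "CDS"),
        "utr": sorted(p for p, r in rmap.items() if r in ("5'UTR", "3'UTR")),
        "intron": sorted(p for p, r in rmap.items() if r == "intron"),
        "splice": sorted(
            p for p, r in rmap.items() if r in ("splice_donor", "splice_acceptor")
        ),
    }
    n = spec.n_variants_per_gene
    counts = {k: int(round(f * n)) for k, f in spec.region_fractions.items()}
    while sum(counts.values()) < n:
        counts["cds"] += 1
    while sum(counts.values()) > n:
        big = max(counts, key=counts.get)
        counts[big] -= 1

    region_term = {
        "5'UTR": "5_prime_UTR_variant",
        "3'UTR": "3_prime_UTR_variant",
        "intron": "intron_variant",
        "splice_donor": "splice_donor_variant",
        "splice_acceptor": "splice_acceptor_variant",
    }
    planted: list[PlantedVariant] = []
    used: set[tuple[int, str, str]] = set()

    def add(pos: int, ref: str, alt: str, region: str, term: str) -> bool:
        if (pos, ref, alt) in used:
            return False
        used.add((pos, ref, alt))
        planted.append(
            PlantedVariant(
                chrom=gene.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene_id=gene.gene_id,
                transcript_id=tr.transcript_id,
                region=region,
                expected_consequence=term,
            )
        )
        return True

    def plant_snv(pos: int, region: str) -> bool:
        ref = genome.fetch(gene.chrom, pos, pos)
        alt = rng.choice([b for b in BASES if b != ref])
        if region == "CDS":
            term = oracle.brute_force_snv_consequence(tr, genome, pos, alt)
        else:
            term = region_term[region]
        return add(pos, ref, alt, region, term)

    cds_set = set(pools["cds"])
    for cls, want in counts.items():
        pool = pools[cls] if pools[cls] else pools["cds"]
        for _ in range(want):
            for _attempt in range(25):
                pos = rng.choice(pool)
                region = rmap[pos]
                if region != "CDS":
                    if plant_snv(pos, region):
                        break
                    continue
                if rng.random() < spec.indel_fraction:
                    length = rng.choice((1, 2, 3))
                    deletion = rng.random() < 0.5
                    anchor = pos
                    if deletion and all(
                        anchor + i in cds_set for i in range(length + 1)
                    ):
                        ref = genome.fetch(gene.chrom, anchor, anchor + length)
                        alt = ref[0]
                    elif not deletion and anchor + 1 in cds_set:
                        ref = genome.fetch(gene.chrom, anchor, anchor)
                        alt = ref + "".join(
                            rng.choice(BASES) for _ in range(length)
                        )
                    else:  # indel would cross the CDS edge; plant a SNV instead
                        if plant_snv(pos, region):
                            break
                        continue
                    term = (
                        "frameshift_variant"
                        if length % 3
                        else ("inframe_deletion" if deletion else "inframe_insertion")
                    )
                    if add(anchor, ref, alt, "CDS", term):
                        break
                elif plant_snv(pos, region):
                    break
    return planted


def _assign_genotypes(
    rng: random.Random, planted: list[PlantedVariant], n_samples: int
) -> None:
    for pv in planted:
        n_carriers = rng.randint(1, max(1, n_samples // 2))
        carriers = set(rng.sample(range(n_samples), n_carriers))
        gts = []
        for i in range(n_samples):
            if i in carriers:
                gts.append("0/1" if rng.random() < 0.7 else "1/1")
            elif rng.random() < 0.1:
                gts.append("./.")
            else:
                gts.append("0/0")
        pv.genotypes = gts


def generate_bundle(spec: FixtureSpec, out_dir: str) -> Bundle:
    """Generate and write a complete fixture bundle under *out_dir*.

    Emits FASTA, GFF3, multi-sample VCF, the protein-feature TSV, one TSV
    per annotation database (under ``annotations/``) and the ground-truth
    sidecar ``truth.tsv``.  Fully deterministic per spec.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    ann_dir = os.path.join(out_dir, "annotations")
    os.makedirs(ann_dir, exist_ok=True)

    genes: list[GeneModel] = []
    all_writes: dict[int, str] = {}
    cursor = spec.intergenic_gap + 1
    for i in range(spec.n_genes):
        gene, writes = _design_gene(rng, i, spec, cursor)
        genes.append(gene)
        all_writes.update(writes)
        cursor = gene.span[1] + spec.intergenic_gap
    contig_len = cursor + spec.intergenic_gap

    seq = [rng.choice(BASES) for _ in range(contig_len)]
    for p, b in all_writes.items():
        seq[p - 1] = b
    genome = Genome({spec.contig: "".join(seq)})

    for gene in genes:
        for tr in gene.transcripts:
            attach_translation(tr, genome)
            if not tr.translatable:  # construction guarantees this never fires
                raise FixtureError(f"generated CDS of {tr.transcript_id} untranslatable")

    planted: list[PlantedVariant] = []
    for gene in genes:
        planted.extend(_plant_variants(rng, gene, genome, spec))
    planted.sort(key=lambda pv: pv.pos)
    _assign_genotypes(rng, planted, spec.n_samples)
    sample_names = [f"S{i + 1}" for i in range(spec.n_samples)]

    fasta = os.path.join(out_dir, "genome.fa")
    with open(fasta, "w") as fh:
        fh.write(f">{spec.contig}\n")
        s = genome.fetch(spec.contig, 1, contig_len)
        for i in range(0, len(s), 70):
            fh.write(s[i : i + 70] + "\n")

    gff3 = os.path.join(out_dir, "genes.gff3")
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {spec.contig} 1 {contig_len}\n")
        for gene in genes:
            s, e = gene.span
            fh.write(
                f"{spec.contig}\ttoy\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id};Name={gene.symbol}\n"
            )
            for tr in gene.transcripts:
                ts, te = tr.span
                attrs = (
                    f"ID={tr.transcript_id};Parent={gene.gene_id};"
                    f"biotype={tr.biotype}"
                )
                if tr.canonical_flag:
                    attrs += ";tag=Ensembl_canonical"
                fh.write(
                    f"{spec.contig}\ttoy\tmRNA\t{ts}\t{te}\t.\t{tr.strand}\t.\t{attrs}\n"
                )
                for j, (xs, xe) in enumerate(tr.exons, 1):
                    fh.write(
                        f"{spec.contig}\ttoy\texon\t{xs}\t{xe}\t.\t{tr.strand}\t.\t"
                        f"ID={tr.transcript_id}.exon{j};Parent={tr.transcript_id}\n"
                    )
                for j, (cs, ce) in enumerate(tr.cds_segments, 1):
                    fh.write(
                        f"{spec.contig}\ttoy\tCDS\t{cs}\t{ce}\t.\t{tr.strand}\t0\t"
                        f"ID={tr.transcript_id}.cds{j};Parent={tr.transcript_id}\n"
                    )

    vcf = os.path.join(out_dir, "variants.vcf")
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=file:///toy/GRCh38.fa\n")
        fh.write(f"##contig=<ID={spec.contig},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for pv in planted:
            fh.write(
                f"{pv.chrom}\t{pv.pos}\t.\t{pv.ref}\t{pv.alt}\t50\tPASS\t.\tGT\t"
                + "\t".join(pv.genotypes)
                + "\n"
            )

    domains_tsv = os.path.join(out_dir, "domains.tsv")
    with open(domains_tsv, "w") as fh:
        fh.write("transcript_id\tlabel\tcategory\taa_start\taa_end\tsource\n")
        for gene in genes:
            tr = gene.transcripts[0]
            plen = tr.protein_length or 0
            if plen < 6:
                continue
            n_dom = rng.randint(1, 2)
            lo = 2
            for k in range(n_dom):
                if lo + 3 > plen - 1:
                    break
                a = rng.randint(lo, max(lo, plen // 2))
                b = rng.randint(a + 2, min(plen - 1, a + max(3, plen // 3)))
                fh.write(
                    f"{tr.transcript_id}\t{gene.symbol}_dom{k + 1}\tdomain\t{a}\t{b}\ttoyDB\n"
                )
                lo = b + 2

    # annotation tables: cover a fraction of planted variants per database
    def covered(fraction: float) -> list[PlantedVariant]:
        k = int(round(fraction * len(planted)))
        return rng.sample(planted, min(k, len(planted)))

    cov = spec.annotation_coverage
    with open(os.path.join(ann_dir, "gnomad.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf\n")
        for pv in sorted(covered(cov["gnomad"]), key=lambda p: p.pos):
            af = round(10 ** rng.uniform(-5, -0.7), 6)
            fh.write(f"{pv.chrom}\t{pv.pos}\t{pv.ref}\t{pv.alt}\t{af}\n")
    with open(os.path.join(ann_dir, "dbsnp.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\trsid\n")
        for pv in sorted(covered(cov["dbsnp"]), key=lambda p: p.pos):
            fh.write(f"{pv.chrom}\t{pv.pos}\t{pv.ref}\t{pv.alt}\trs{rng.randrange(10**4, 10**8)}\n")
    with open(os.path.join(ann_dir, "clinvar.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsignificance\n")
        for pv in sorted(covered(cov["clinvar"]), key=lambda p: p.pos):
            fh.write(
                f"{pv.chrom}\t{pv.pos}\t{pv.ref}\t{pv.alt}\t{rng.choice(CLINVAR_CLASSES)}\n"
            )
    with open(os.path.join(ann_dir, "cosmic.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcosmic_id\n")
        for pv in sorted(covered(cov["cosmic"]), key=lambda p: p.pos):
            fh.write(f"{pv.chrom}\t{pv.pos}\t{pv.ref}\t{pv.alt}\tCOSV{rng.randrange(10**7):07d}\n")
    with open(os.path.join(ann_dir, "scores.tsv"), "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tsift_score\tsift_class\t"
            "polyphen_score\tpolyphen_class\n"
        )
        for pv in sorted(covered(cov["scores"]), key=lambda p: p.pos):
            sift = round(rng.random(), 3)
            sclass = "deleterious" if sift <= 0.05 else "tolerated"
            pp = round(rng.random(), 3)
            pclass = (
                "probably_damaging"
                if pp >= 0.908
                else "possibly_damaging" if pp >= 0.446 else "benign"
            )
            fh.write(
                f"{pv.chrom}\t{pv.pos}\t{pv.ref}\t{pv.alt}\t{sift}\t{sclass}\t{pp}\t{pclass}\n"
            )
    with open(os.path.join(ann_dir, "terms.tsv"), "w") as fh:
        fh.write("symbol\tontology\tterm_id\tterm_label\n")
        for gene in genes:
            for _ in range(rng.randint(2, 3)):
                fh.write(
                    f"{gene.symbol}\tGO\tGO:{rng.randrange(10**7):07d}\ttoy process\n"
                )
            for _ in range(rng.randint(1, 2)):
                fh.write(
                    f"{gene.symbol}\tHPO\tHP:{rng.randrange(10**7):07d}\ttoy phenotype\n"
                )

    truth_tsv = os.path.join(out_dir, "truth.tsv")
    with open(truth_tsv, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tgene_id\ttranscript_id\tregion\texpected_consequence\n"
        )
        for pv in planted:
            fh.write(
                f"{pv.chrom}\t{pv.pos}\t{pv.ref}\t{pv.alt}\t{pv.gene_id}\t"
                f"{pv.transcript_id}\t{pv.region}\t{pv.expected_consequence}\n"
            )

    return Bundle(
        directory=out_dir,
        fasta=fasta,
        gff3=gff3,
        vcf=vcf,
        domains_tsv=domains_tsv,
        annotation_dir=ann_dir,
        truth_tsv=truth_tsv,
        genes=genes,
        genome=genome,
        planted=planted,
        sample_names=sample_names,
    )
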