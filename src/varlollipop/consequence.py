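"""Transcript-level consequence calls and per-variant carrier statistics.

This is the local stand-in for a VEP query: every (variant, transcript) pair
receives exactly one Sequence Ontology term from the supported set, plus —
when the variant touches the coding sequence — the CDS offset, protein
position, amino-acid change and a short protein HGVS string.

Classification of a coding SNV works on the single affected codon: the codon
is sliced out of the spliced CDS, the alternate base substituted
(strand-aware), and both codons translated.  Precedence when a change could
carry several labels: synonymous (no amino-acid change) first, then
stop_gained, stop_lost, start_lost, missense.  Indels use the VCF
anchor-base convention and the length-difference rule (multiple of three ->
in-frame, else frameshift).  Splice terms apply only to the two intronic
bases flanking an exon in transcription order; a coding base near a junction
stays CDS-classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .gene_model import Genome, Transcript
from .vcf_io import Genotype, VariantRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: supported Sequence Ontology terms, most severe first
SEVERITY_ORDER = [
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
]

SEVERITY_RANK = {term: len(SEVERITY_ORDER) - i for i, term in enumerate(SEVERITY_ORDER)}

#: how far outside the transcript span up/downstream terms still apply (bp)
FLANK_BP = 5000

_REGION_TERM = {
    "5'UTR": "5_prime_UTR_variant",
    "3'UTR": "3_prime_UTR_variant",
    "intron": "intron_variant",
    "splice_donor": "splice_donor_variant",
    "splice_acceptor": "splice_acceptor_variant",
}


class AnnotationError(Exception):
    pass


@dataclass
class AnnotatedVariant:
    variant: VariantRecord
    transcript_id: str
    consequence_term: str
    cds_pos: int | None = None
    protein_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    hgvs_p: str | None = None
    carrier_frequency: float = 0.0
    carrier_samples: list[tuple[str, str]] = field(default_factory=list)

    @property
    def key(self):
        return self.variant.key

    @property
    def severity_rank(self) -> int:
        return SEVERITY_RANK[self.consequence_term]


def project_to_cds(pos: int, transcript: Transcript) -> tuple[str, int | None]:
    """Region label and (for CDS hits) the 1-based spliced-CDS offset.

    The offset counts in translation order, so it is strand-aware.  Splice
    donor bases are the first two intronic bases after an exon in
    transcription order; acceptor bases the last two before one.
    """
    lo, hi = transcript.span
    if not lo <= pos <= hi:
        raise AnnotationError(
            f"position {pos} outside transcript span {lo}-{hi}"
        )
    if not transcript.is_coding:
        raise AnnotationError(
            f"{transcript.transcript_id} is non-coding; no CDS projection"
        )
    plus = transcript.strand == "+"

    in_exon = any(s <= pos <= e for s, e in transcript.exons)
    if in_exon:
        cds_before = 0
        for s, e in transcript.cds_segments:
            if s <= pos <= e:
                if plus:
                    cds_pos = cds_before + (pos - s) + 1
                else:
                    after = sum(
                        e2 - s2 + 1
                        for s2, e2 in transcript.cds_segments
                        if s2 > e
                    )
                    cds_pos = after + (e - pos) + 1
                return ("CDS", cds_pos)
            cds_before += e - s + 1
        cds_lo = transcript.cds_segments[0][0]
        cds_hi = transcript.cds_segments[-1][1]
        if (plus and pos < cds_lo) or (not plus and pos > cds_hi):
            return ("5'UTR", None)
        return ("3'UTR", None)

    # intronic: check the two transcription-order flanking bases of each junction
    for (s0, e0), (s1, e1) in zip(transcript.exons, transcript.exons[1:]):
        if not e0 < pos < s1:
            continue
        if plus:
            if pos - e0 <= 2:
                return ("splice_donor", None)
            if s1 - pos <= 2:
                return ("splice_acceptor", None)
        else:
            if s1 - pos <= 2:
                return ("splice_donor", None)
            if pos - e0 <= 2:
                return ("splice_acceptor", None)
        return ("intron", None)
    raise AnnotationError(f"position {pos} not locatable in transcript")


def carrier_stats(
    variant: VariantRecord, sample_names: list[str] | None = None
) -> tuple[float, list[tuple[str, str]]]:
    """Carrier frequency among VCF samples and per-carrier zygosity.

    A sample carries the variant iff at least one allele index equals 1.
    Missing genotypes (``./.``) count as non-carriers; the denominator is
    always the full sample count.
    """
    n = len(sample_names) if sample_names is not None else len(variant.genotypes)
    carriers: list[tuple[str, str]] = []
    for g in variant.genotypes:
        alt = sum(1 for a in g.allele_indices if a == 1)
        if alt == 0:
            continue
        called = [a for a in g.allele_indices if a is not None]
        if alt == 1:
            zyg = "het"
        elif all(a == 1 for a in called):
            zyg = "hom"
        else:
            zyg = "het"
        carriers.append((g.sample_id, zyg))
    freq = len(carriers) / n if n else 0.0
    return freq, carriers


def _codon_call(
    transcript: Transcript, cds_pos: int, alt_base: str
) -> tuple[str, int, str, str]:
    """Term, protein position and aa change for a coding SNV (one codon)."""
    cds = transcript.cds_sequence
    assert cds is not None
    ci = (cds_pos - 1) // 3
    off = (cds_pos - 1) % 3
    ref_codon = cds[ci * 3 : ci * 3 + 3]
    alt_stranded = (
        alt_base if transcript.strand == "+" else alt_base.translate(COMPLEMENT)
    )
    alt_codon = ref_codon[:off] + alt_stranded + ref_codon[off + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        term = "synonymous_variant"
    elif aa_alt == "*":
        term = "stop_gained"
    elif aa_ref == "*":
        term = "stop_lost"
    elif ci == 0:
        term = "start_lost"
    else:
        term = "missense_variant"
    return term, ci + 1, aa_ref, aa_alt


def annotate(
    variant: VariantRecord, transcript: Transcript, genome: Genome
) -> AnnotatedVariant:
    """Full consequence annotation of one variant against one transcript.

    The reference allele is checked against the genome (a mismatch is an
    error: it means variant and gene model disagree on the assembly).
    Variants outside the transcript span but within 5 kb receive
    upstream/downstream terms relative to the strand.
    """
    freq, carriers = carrier_stats(variant)

    def _done(term, cds_pos=None, protein_pos=None, aa_ref=None, aa_alt=None, hgvs=None):
        return AnnotatedVariant(
            variant=variant,
            transcript_id=transcript.transcript_id,
            consequence_term=term,
            cds_pos=cds_pos,
            protein_pos=protein_pos,
            aa_ref=aa_ref,
            aa_alt=aa_alt,
            hgvs_p=hgvs,
            carrier_frequency=freq,
            carrier_samples=carriers,
        )

    lo, hi = transcript.span
    pos, ref, alt = variant.pos, variant.ref_allele, variant.alt_allele
    if pos < lo or pos > hi:
        if pos < lo - FLANK_BP or pos > hi + FLANK_BP:
            raise AnnotationError(
                f"{variant.chrom}:{pos} is >{FLANK_BP} bp from {transcript.transcript_id}"
            )
        left = pos < lo
        upstream = left if transcript.strand == "+" else not left
        return _done("upstream_gene_variant" if upstream else "downstream_gene_variant")

    genome_ref = genome.fetch(variant.chrom, pos, pos + len(ref) - 1)
    if genome_ref != ref:
        raise AnnotationError(
            f"reference mismatch at {variant.chrom}:{pos}: "
            f"VCF says {ref!r}, genome says {genome_ref!r}"
        )

    if len(ref) == 1 and len(alt) == 1:
        region, cds_pos = project_to_cds(pos, transcript)
        if region != "CDS":
            return _done(_REGION_TERM[region])
        term, ppos, aa_ref, aa_alt = _codon_call(transcript, cds_pos, alt)
        hgvs = None
        if term == "missense_variant":
            hgvs = f"p.{aa_ref}{ppos}{aa_alt}"
        elif term == "stop_gained":
            hgvs = f"p.{aa_ref}{ppos}*"
        return _done(term, cds_pos, ppos, aa_ref, aa_alt, hgvs)

    # indel / MNV, anchor-base convention: first changed base
    diff = len(alt) - len(ref)
    if diff != 0 and ref[0] == alt[0]:
        change_pos = pos + 1
    else:
        change_pos = pos
    change_pos = min(max(change_pos, lo), hi)
    region, cds_pos = project_to_cds(change_pos, transcript)
    if region != "CDS":
        return _done(_REGION_TERM[region])
    if diff == 0:
        # MNV: within one codon treated as a single substitution event
        ci = (cds_pos - 1) // 3
        cds = transcript.cds_sequence
        positions = transcript.cds_positions()
        codon_genomic = set(positions[ci * 3 : ci * 3 + 3])
        changed = {pos + i for i in range(len(ref)) if ref[i] != alt[i]}
        if changed <= codon_genomic:
            ref_codon = cds[ci * 3 : ci * 3 + 3]
            alt_codon = list(ref_codon)
            for i, (r, a) in enumerate(zip(ref, alt)):
                if r == a:
                    continue
                p = pos + i
                idx = positions.index(p) - ci * 3
                alt_codon[idx] = (
                    a if transcript.strand == "+" else a.translate(COMPLEMENT)
                )
            aa_ref = str(Seq(ref_codon).translate())
            aa_alt = str(Seq("".join(alt_codon)).translate())
            if aa_ref == aa_alt:
                term = "synonymous_variant"
            elif aa_alt == "*":
                term = "stop_gained"
            else:
                term = "missense_variant"
            return _done(term, cds_pos, ci + 1, aa_ref, aa_alt)
        return _done("missense_variant", cds_pos, ci + 1)
    ppos = (cds_pos - 1) // 3 + 1
    if diff % 3 != 0:
        return _done("frameshift_variant", cds_pos, ppos)
    term = "inframe_insertion" if diff > 0 else "inframe_deletion"
    return _done(term, cds_pos, ppos)


def annotate_all(
    records,
    transcript: Transcript,
    genome: Genome,
) -> list[AnnotatedVariant]:
    """Annotate every record overlapping the transcript span (flanks excluded)."""
    lo, hi = transcript.span
    out = []
    for rec in records:
        if rec.chrom == transcript.chrom and lo <= rec.pos <= hi:
            out.append(annotate(rec, transcript, genome))
    return out
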