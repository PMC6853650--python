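"""Brute-force reference implementations used as independent cross-checks.

These functions deliberately avoid the arithmetic shortcuts of the main
consequence engine and interval index: regions are classified by fully
enumerating every genomic position of a transcript, consequences by
rebuilding the whole mutant CDS and translating both proteins, and overlap
queries by linear scan.  The fixture generator stamps its ground-truth
sidecar with these, and the test suite holds the fast paths to them.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from Bio.Seq import Seq

from .gene_model import GeneModel, Genome, Transcript

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def region_map(transcript: Transcript) -> dict[int, str]:
    """Classify every genomic position within the transcript span.

    Built by explicit set enumeration: exon/CDS membership, the two intronic
    bases flanking each exon boundary in transcription order (donor after an
    exon, acceptor before one), UTR sidedness from transcription order.
    """
    exon_pos = {p for s, e in transcript.exons for p in range(s, e + 1)}
    cds_pos = {p for s, e in transcript.cds_segments for p in range(s, e + 1)}
    lo, hi = transcript.span
    intron_pos = {p for p in range(lo, hi + 1) if p not in exon_pos}

    donors: set[int] = set()
    acceptors: set[int] = set()
    exons = transcript.exons
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        intron = range(e0 + 1, s1)
        if not intron:
            continue
        if transcript.strand == "+":
            donors.update(list(intron)[:2])
            acceptors.update(list(intron)[-2:])
        else:
            # transcription runs right-to-left: the donor side of this intron
            # is its high-coordinate end (adjacent to the transcription-earlier exon)
            donors.update(list(intron)[-2:])
            acceptors.update(list(intron)[:2])

    out: dict[int, str] = {}
    if cds_pos:
        cds_lo, cds_hi = min(cds_pos), max(cds_pos)
    for p in range(lo, hi + 1):
        if p in cds_pos:
            out[p] = "CDS"
        elif p in exon_pos:
            if not cds_pos:
                out[p] = "non_coding_exon"
            elif (transcript.strand == "+" and p < cds_lo) or (
                transcript.strand == "-" and p > cds_hi
            ):
                out[p] = "5'UTR"
            else:
                out[p] = "3'UTR"
        elif p in donors:
            out[p] = "splice_donor"
        elif p in acceptors:
            out[p] = "splice_acceptor"
        else:
            assert p in intron_pos
            out[p] = "intron"
    return out


def mutant_cds(
    transcript: Transcript, genome: Genome, pos: int, alt_base: str
) -> str:
    """Rebuild the full spliced CDS with a single-base substitution applied."""
    bases = []
    for p in transcript.cds_positions():
        b = genome.fetch(transcript.chrom, p, p)
        if p == pos:
            b = alt_base
        if transcript.strand == "-":
            b = b.translate(COMPLEMENT)
        bases.append(b)
    return "".join(bases)


def classify_proteins(ref_cds: str, mut_cds: str) -> str:
    """Sequence Ontology term for a CDS SNV from full-length translations.

    Per changed codon: identical translations are synonymous; a codon turned
    stop is stop_gained; the terminal stop turned coding is stop_lost; a
    changed initiator codon is start_lost; anything else missense.
    """
    ref_p = str(Seq(ref_cds).translate())
    mut_p = str(Seq(mut_cds).translate())
    if ref_p == mut_p:
        return "synonymous_variant"
    j = next(i for i, (a, b) in enumerate(zip(ref_p, mut_p)) if a != b)
    if mut_p[j] == "*":
        return "stop_gained"
    if ref_p[j] == "*":
        return "stop_lost"
    if j == 0:
        return "start_lost"
    return "missense_variant"


def brute_force_snv_consequence(
    transcript: Transcript, genome: Genome, pos: int, alt_base: str
) -> str:
    """Consequence of a SNV anywhere in the transcript span, by enumeration."""
    region = region_map(transcript)[pos]
    mapping = {
        "5'UTR": "5_prime_UTR_variant",
        "3'UTR": "3_prime_UTR_variant",
        "intron": "intron_variant",
        "splice_donor": "splice_donor_variant",
        "splice_acceptor": "splice_acceptor_variant",
    }
    if region != "CDS":
        return mapping[region]
    ref_cds = transcript.cds_sequence
    assert ref_cds is not None
    return classify_proteins(ref_cds, mutant_cds(transcript, genome, pos, alt_base))


def linear_scan_query(
    genes: Iterable[GeneModel], chrom: str, pos: int
) -> set[str]:
    """Stabbing query by checking every gene span — the index oracle."""
    return {
        g.gene_id
        for g in genes
        if g.chrom == chrom and g.span[0] <= pos <= g.span[1]
    }
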