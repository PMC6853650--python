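"""Gene model loading, translation, canonical choice and the interval index."""

import random

import pytest

from conftest import TOY_CDS, TOY_PROTEIN, build_minus_toy, build_plus_toy, revcomp
from varlollipop import oracle
from varlollipop.gene_model import (
    GeneModel,
    GeneModelError,
    Genome,
    Transcript,
    attach_translation,
    build_index,
    genes_with_variants,
    load_gene_models,
    select_canonical,
    spliced_cds,
)
from varlollipop.vcf_io import Genotype, VariantRecord


def _mk_transcript(tid, cds_len, flagged=False):
    return Transcript(
        transcript_id=tid,
        biotype="protein_coding",
        chrom="chrT",
        strand="+",
        exons=[(1, cds_len + 20)],
        cds_segments=[(11, 10 + cds_len)],
        canonical_flag=flagged,
        protein_sequence="M" * (cds_len // 3 - 1),
        translatable=True,
    )


class TestTranslation:
    def test_toy_plus_protein_hand_translated(self, plus_toy):
        gene, _ = plus_toy
        tr = gene.transcripts[0]
        assert tr.cds_sequence == TOY_CDS
        assert tr.protein_sequence == TOY_PROTEIN
        assert tr.protein_length == 9

    def test_minus_strand_yields_identical_protein(self, minus_toy):
        gene, _ = minus_toy
        tr = gene.transcripts[0]
        assert tr.cds_sequence == TOY_CDS
        assert tr.protein_sequence == TOY_PROTEIN

    def test_cds_not_multiple_of_three_flagged(self):
        seq = "A" * 10 + "ATG" + "GCTGAATTCGGACATAAACCCGTAT"  # 28 nt CDS
        genome = Genome({"chrT": seq + "A" * 10})
        tr = Transcript("Tx", "protein_coding", "chrT", "+", [(1, 48)], [(11, 39)])
        attach_translation(tr, genome)
        assert not tr.translatable

    def test_internal_stop_flagged(self):
        cds = "ATGTAAGCTTGA"  # stop at codon 2
        genome = Genome({"chrT": "A" * 10 + cds + "A" * 10})
        tr = Transcript("Tx", "protein_coding", "chrT", "+", [(1, 32)], [(11, 22)])
        attach_translation(tr, genome)
        assert not tr.translatable

    def test_cds_beyond_contig_is_fatal(self):
        genome = Genome({"chrT": "A" * 20})
        tr = Transcript("Tx", "protein_coding", "chrT", "+", [(1, 50)], [(11, 40)])
        with pytest.raises(GeneModelError, match="beyond contig"):
            attach_translation(tr, genome)

    def test_bundle_translation_sanity(self, bundle):
        """protein_length = CDS length / 3 - 1 for every generated transcript."""
        for gene in bundle.genes:
            for tr in gene.transcripts:
                assert tr.translatable
                assert tr.protein_length == tr.cds_length // 3 - 1


class TestGff3Loading:
    def test_bundle_gff3_reproduces_in_memory_models(self, bundle):
        genes, genome = load_gene_models(bundle.gff3, bundle.fasta)
        assert {g.gene_id for g in genes} == {g.gene_id for g in bundle.genes}
        by_id = {g.gene_id: g for g in genes}
        for orig in bundle.genes:
            loaded = by_id[orig.gene_id]
            lt, ot = loaded.transcripts[0], orig.transcripts[0]
            assert lt.exons == ot.exons
            assert lt.cds_segments == ot.cds_segments
            assert lt.protein_sequence == ot.protein_sequence
            assert lt.canonical_flag


class TestSelectCanonical:
    def test_flagged_transcript_wins(self):
        gene = GeneModel("G", "S", "chrT", "+", (1, 100), [
            _mk_transcript("T1", 300), _mk_transcript("T2", 450, flagged=True),
            _mk_transcript("T3", 600),
        ])
        assert select_canonical(gene).transcript_id == "T2"

    def test_longest_cds_without_flags(self):
        gene = GeneModel("G", "S", "chrT", "+", (1, 100), [
            _mk_transcript("T1", 300), _mk_transcript("T2", 450),
        ])
        assert select_canonical(gene).transcript_id == "T2"

    def test_tie_broken_by_smallest_id(self):
        gene = GeneModel("G", "S", "chrT", "+", (1, 100), [
            _mk_transcript("T2", 300), _mk_transcript("T1", 300),
        ])
        assert select_canonical(gene).transcript_id == "T1"

    def test_no_coding_transcript_is_error(self):
        tr = _mk_transcript("T1", 300)
        tr.translatable = False
        gene = GeneModel("G", "S", "chrT", "+", (1, 100), [tr])
        with pytest.raises(GeneModelError, match="no plottable"):
            select_canonical(gene)


def _random_gene_set(rng, n=50):
    genes = []
    for i in range(n):
        chrom = rng.choice(["chrT", "chrU"])
        start = rng.randint(1, 5000)
        end = start + rng.randint(10, 800)
        tr = Transcript(f"T{i}", "protein_coding", chrom, "+", [(start, end)])
        genes.append(GeneModel(f"G{i}", f"S{i}", chrom, "+", (start, end), [tr]))
    return genes


class TestGeneIndex:
    def test_overlapping_spans_both_returned(self):
        genes = [
            GeneModel("A", "A", "chrT", "+", (100, 200), []),
            GeneModel("B", "B", "chrT", "+", (150, 300), []),
            GeneModel("C", "C", "chrT", "+", (400, 500), []),
        ]
        idx = build_index(genes)
        assert idx.query("chrT", 160) == {"A", "B"}
        assert idx.query("chrT", 350) == set()
        assert idx.query("chrQ", 160) == set()

    def test_matches_linear_scan_on_random_set(self):
        rng = random.Random(7)
        genes = _random_gene_set(rng)
        idx = build_index(genes)
        for _ in range(200):
            chrom = rng.choice(["chrT", "chrU", "chrV"])
            pos = rng.randint(1, 6000)
            assert idx.query(chrom, pos) == oracle.linear_scan_query(genes, chrom, pos)

    def test_span_boundaries_inclusive(self):
        genes = [GeneModel("A", "A", "chrT", "+", (100, 200), [])]
        idx = build_index(genes)
        assert idx.query("chrT", 100) == {"A"}
        assert idx.query("chrT", 200) == {"A"}
        assert idx.query("chrT", 99) == set()
        assert idx.query("chrT", 201) == set()


def _rec(pos, chrom="chrT", ref="A", alt="C", carriers=()):
    gts = tuple(
        Genotype(sample_id=s, allele_indices=(0, 1)) for s in carriers
    )
    return VariantRecord(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt, genotypes=gts)


class TestGenesWithVariants:
    def test_counts_and_sorting(self):
        genes = [
            GeneModel("B", "BETA", "chrT", "+", (100, 200), []),
            GeneModel("A", "ALPHA", "chrT", "+", (300, 400), []),
        ]
        idx = build_index(genes)
        recs = [_rec(110, carriers=["s1"]), _rec(120, carriers=["s1", "s2"]),
                _rec(130), _rec(350, carriers=["s3"])]
        hits = genes_with_variants(idx, recs)
        assert [h.symbol for h in hits] == ["ALPHA", "BETA"]
        beta = hits[1]
        assert beta.variant_count == 3
        assert beta.carrier_sample_count == 2

    def test_variant_in_overlap_counts_in_both(self):
        genes = [
            GeneModel("A", "A", "chrT", "+", (100, 200), []),
            GeneModel("B", "B", "chrT", "+", (150, 300), []),
        ]
        idx = build_index(genes)
        hits = genes_with_variants(idx, [_rec(160)])
        assert {h.gene_id for h in hits} == {"A", "B"}
        assert all(h.variant_count == 1 for h in hits)

    def test_duplicate_records_counted_once(self):
        genes = [GeneModel("A", "A", "chrT", "+", (100, 200), [])]
        idx = build_index(genes)
        hits = genes_with_variants(idx, [_rec(110), _rec(110)])
        assert hits[0].variant_count == 1

    def test_empty_records_empty_list(self):
        idx = build_index([GeneModel("A", "A", "chrT", "+", (100, 200), [])])
        assert genes_with_variants(idx, []) == []


class TestStrandSymmetry:
    def test_mirrored_genome_preserves_all_proteins(self, bundle):
        """Reverse-complementing the contig and flipping coordinates/strands
        must leave every protein unchanged."""
        contig = bundle.genes[0].chrom
        L = bundle.genome.contig_length(contig)
        mirrored = Genome({contig: revcomp(bundle.genome.fetch(contig, 1, L))})

        def flip(iv):
            s, e = iv
            return (L - e + 1, L - s + 1)

        for gene in bundle.genes:
            tr = gene.transcripts[0]
            flipped = Transcript(
                transcript_id=tr.transcript_id,
                biotype=tr.biotype,
                chrom=contig,
                strand="-" if tr.strand == "+" else "+",
                exons=[flip(iv) for iv in tr.exons],
                cds_segments=[flip(iv) for iv in tr.cds_segments],
            )
            attach_translation(flipped, mirrored)
            assert flipped.translatable
            assert flipped.protein_sequence == tr.protein_sequence
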