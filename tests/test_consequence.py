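"""Consequence engine: coordinate projection, codon calls, carrier stats."""

import pytest

from varlollipop import oracle
from varlollipop.consequence import (
    SEVERITY_RANK,
    AnnotationError,
    annotate,
    carrier_stats,
    project_to_cds,
)
from varlollipop.gene_model import Genome, Transcript, attach_translation
from varlollipop.vcf_io import Genotype, VariantRecord


def _rec(pos, ref, alt, genotypes=(), chrom="chrT"):
    return VariantRecord(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                         genotypes=tuple(genotypes))


def _gt(sample, *alleles, phased=False):
    return Genotype(sample_id=sample, allele_indices=alleles, phased=phased)


class TestProjectToCds:
    def test_first_and_seventh_cds_base(self, plus_toy):
        tr = plus_toy[0].transcripts[0]
        assert project_to_cds(111, tr) == ("CDS", 1)
        assert project_to_cds(117, tr) == ("CDS", 7)

    def test_utr5_before_cds_on_plus(self, plus_toy):
        tr = plus_toy[0].transcripts[0]
        assert project_to_cds(105, tr) == ("5'UTR", None)
        assert project_to_cds(145, tr) == ("3'UTR", None)

    def test_minus_strand_cds_offsets(self, minus_toy):
        tr = minus_toy[0].transcripts[0]
        # CDS 121-150 read right-to-left: genomic 150 is CDS base 1
        assert project_to_cds(150, tr) == ("CDS", 1)
        assert project_to_cds(144, tr) == ("CDS", 7)
        assert project_to_cds(155, tr) == ("5'UTR", None)
        assert project_to_cds(110, tr) == ("3'UTR", None)

    def test_minus_strand_splice_donor_after_first_exon(self):
        # two exons on minus: transcription starts in the right exon, so the
        # first intronic base 3' of it (genomic end of the intron) is a donor
        genome = Genome({"chrT": "A" * 300})
        tr = Transcript("T2m", "protein_coding", "chrT", "-",
                        exons=[(101, 130), (171, 200)],
                        cds_segments=[(110, 130), (171, 190)])
        assert project_to_cds(170, tr) == ("splice_donor", None)
        assert project_to_cds(169, tr) == ("splice_donor", None)
        assert project_to_cds(131, tr) == ("splice_acceptor", None)
        assert project_to_cds(132, tr) == ("splice_acceptor", None)
        assert project_to_cds(150, tr) == ("intron", None)

    def test_outside_span_is_error(self, plus_toy):
        tr = plus_toy[0].transcripts[0]
        with pytest.raises(AnnotationError, match="outside"):
            project_to_cds(50, tr)

    def test_agrees_with_enumeration_oracle_on_bundle(self, bundle):
        """Arithmetic projection equals position-set enumeration everywhere."""
        for gene in bundle.genes:
            tr = gene.transcripts[0]
            rmap = oracle.region_map(tr)
            for pos, region in rmap.items():
                got_region, cds_pos = project_to_cds(pos, tr)
                assert got_region == region, f"{tr.transcript_id}:{pos}"
                if region == "CDS":
                    # cds_pos indexes the spliced CDS in translation order
                    assert tr.cds_positions()[cds_pos - 1] == pos


class TestAnnotateSnv:
    def test_stop_gained_with_hgvs(self, plus_toy):
        gene, genome = plus_toy
        av = annotate(_rec(117, "G", "T"), gene.transcripts[0], genome)
        assert av.consequence_term == "stop_gained"
        assert av.protein_pos == 3
        assert av.hgvs_p == "p.E3*"

    def test_synonymous_third_codon(self, plus_toy):
        gene, genome = plus_toy
        av = annotate(_rec(119, "A", "G"), gene.transcripts[0], genome)
        assert av.consequence_term == "synonymous_variant"
        assert av.protein_pos == 3

    def test_missense_with_hgvs(self, plus_toy):
        gene, genome = plus_toy
        # codon 2 GCT -> GTT = A2V
        av = annotate(_rec(115, "C", "T"), gene.transcripts[0], genome)
        assert av.consequence_term == "missense_variant"
        assert av.hgvs_p == "p.A2V"

    def test_start_lost(self, plus_toy):
        gene, genome = plus_toy
        av = annotate(_rec(111, "A", "G"), gene.transcripts[0], genome)
        assert av.consequence_term == "start_lost"

    def test_stop_lost(self, plus_toy):
        gene, genome = plus_toy
        # terminal codon TGA at 138-140; TGA->TGG = Trp
        av = annotate(_rec(140, "A", "G"), gene.transcripts[0], genome)
        assert av.consequence_term == "stop_lost"

    def test_reference_mismatch_names_position(self, plus_toy):
        gene, genome = plus_toy
        with pytest.raises(AnnotationError, match="reference mismatch at chrT:117"):
            annotate(_rec(117, "A", "T"), gene.transcripts[0], genome)

    def test_upstream_and_downstream_flanks(self, plus_toy):
        gene, genome = plus_toy
        tr = gene.transcripts[0]
        assert annotate(_rec(60, "A", "C"), tr, genome).consequence_term == \
            "upstream_gene_variant"
        assert annotate(_rec(180, "C", "T"), tr, genome).consequence_term == \
            "downstream_gene_variant"

    def test_flanks_swap_on_minus_strand(self, minus_toy):
        gene, genome = minus_toy
        tr = gene.transcripts[0]
        assert annotate(_rec(60, "A", "C"), tr, genome).consequence_term == \
            "downstream_gene_variant"
        assert annotate(_rec(180, "C", "T"), tr, genome).consequence_term == \
            "upstream_gene_variant"

    def test_beyond_flank_is_error(self, plus_toy):
        gene, genome = plus_toy
        with pytest.raises(AnnotationError):
            annotate(_rec(9000, "A", "C", chrom="chrT"), gene.transcripts[0], genome)


class TestAnnotateIndel:
    def test_one_bp_deletion_is_frameshift(self, plus_toy):
        gene, genome = plus_toy
        # anchor at CDS pos 10 (genomic 120), deleting CDS pos 11
        ref = genome.fetch("chrT", 120, 121)
        av = annotate(_rec(120, ref, ref[0]), gene.transcripts[0], genome)
        assert av.consequence_term == "frameshift_variant"

    def test_three_bp_deletion_inframe(self, plus_toy):
        gene, genome = plus_toy
        ref = genome.fetch("chrT", 120, 123)
        av = annotate(_rec(120, ref, ref[0]), gene.transcripts[0], genome)
        assert av.consequence_term == "inframe_deletion"

    def test_insertion_length_rule(self, plus_toy):
        gene, genome = plus_toy
        ref = genome.fetch("chrT", 120, 120)
        assert annotate(_rec(120, ref, ref + "AT"), gene.transcripts[0], genome
                        ).consequence_term == "frameshift_variant"
        assert annotate(_rec(120, ref, ref + "GCA"), gene.transcripts[0], genome
                        ).consequence_term == "inframe_insertion"

    def test_mnv_within_one_codon_classified_as_substitution(self, plus_toy):
        gene, genome = plus_toy
        # codon 3 GAA (117-119) -> TAA: stop via a 2-base MNV at 117-118
        ref = genome.fetch("chrT", 117, 118)
        av = annotate(_rec(117, ref, "TA"), gene.transcripts[0], genome)
        assert av.consequence_term == "stop_gained"

    def test_utr_indel_gets_region_term(self, plus_toy):
        gene, genome = plus_toy
        ref = genome.fetch("chrT", 103, 104)
        av = annotate(_rec(103, ref, ref[0]), gene.transcripts[0], genome)
        assert av.consequence_term == "5_prime_UTR_variant"


class TestOracleEquivalence:
    @pytest.mark.parametrize("which", ["plus", "minus"])
    def test_every_cds_snv_matches_rebuild_translate_oracle(
        self, which, plus_toy, minus_toy
    ):
        gene, genome = plus_toy if which == "plus" else minus_toy
        tr = gene.transcripts[0]
        for pos in tr.cds_positions():
            ref = genome.fetch("chrT", pos, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                expected = oracle.brute_force_snv_consequence(tr, genome, pos, alt)
                got = annotate(_rec(pos, ref, alt), tr, genome).consequence_term
                assert got == expected, f"{which} {pos} {ref}>{alt}"

    def test_synonymous_degeneracy_count_matches_oracle(self, plus_toy):
        gene, genome = plus_toy
        tr = gene.transcripts[0]
        n_engine = n_oracle = 0
        for pos in tr.cds_positions():
            ref = genome.fetch("chrT", pos, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                if annotate(_rec(pos, ref, alt), tr, genome).consequence_term \
                        == "synonymous_variant":
                    n_engine += 1
                if oracle.brute_force_snv_consequence(tr, genome, pos, alt) \
                        == "synonymous_variant":
                    n_oracle += 1
        assert n_engine == n_oracle > 0


class TestCarrierStats:
    def test_mixed_cohort(self):
        gts = [_gt("s1", 0, 1), _gt("s2", 0, 1), _gt("s3", 1, 1)] + [
            _gt(f"s{i}", 0, 0) for i in range(4, 11)
        ]
        freq, carriers = carrier_stats(_rec(10, "A", "C", gts))
        assert freq == pytest.approx(0.3)
        assert carriers == [("s1", "het"), ("s2", "het"), ("s3", "hom")]

    def test_all_missing_are_non_carriers(self):
        gts = [_gt(f"s{i}", None, None) for i in range(5)]
        freq, carriers = carrier_stats(_rec(10, "A", "C", gts))
        assert freq == 0.0 and carriers == []

    def test_single_phased_hom(self):
        freq, carriers = carrier_stats(_rec(10, "A", "C", [_gt("s1", 1, 1, phased=True)]))
        assert freq == 1.0 and carriers == [("s1", "hom")]

    def test_frequency_equals_carriers_over_samples(self, bundle):
        from varlollipop.vcf_io import parse_vcf

        _, records = parse_vcf(bundle.vcf)
        for rec in records:
            freq, carriers = carrier_stats(rec)
            assert freq == len(carriers) / len(bundle.sample_names)
            assert 0.0 <= freq <= 1.0


def test_severity_ranks_cover_all_terms():
    assert SEVERITY_RANK["stop_gained"] > SEVERITY_RANK["missense_variant"]
    assert SEVERITY_RANK["missense_variant"] > SEVERITY_RANK["synonymous_variant"]
    assert SEVERITY_RANK["synonymous_variant"] > SEVERITY_RANK["intron_variant"]
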