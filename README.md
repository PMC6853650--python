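# varlollipop

Local, headless prioritization and protein-level visualization of variants
from exome sequencing studies.

Identifying disease-relevant variants in an exome VCF usually means juggling
an annotation tool, several population and clinical databases, and a plotting
step — and, for patient data, worrying about what leaves the machine.
`varlollipop` runs the whole chain offline: it parses and validates a
multi-sample VCF, detects the genome assembly from the header, finds the
genes carrying variants with a per-chromosome interval tree, computes each
variant's transcript consequence and protein change from local gene models
(GFF3 + FASTA), joins local stand-ins for population-frequency, rsID,
clinical-significance and somatic databases, filters, and draws a lollipop
diagram of the canonical transcript's protein as deterministic SVG
(optionally PNG). It is meant for bioinformaticians and lab scientists who
want scriptable, reproducible variant triage on data that must not be
uploaded anywhere.

## The method in brief

For a bi-allelic variant at genomic position *g* against a transcript with
spliced CDS *C* (read 5'→3', reverse-complemented on the minus strand), the
engine projects *g* to the 1-based CDS offset *c*, takes codon
⌈*c*/3⌉, substitutes the alternate base, and translates both codons with
the standard genetic code. Classification follows Sequence Ontology terms
with precedence synonymous → stop_gained → stop_lost → start_lost →
missense for substitutions; indels use the VCF anchor-base convention and
the length rule (|Δ| mod 3 = 0 → in-frame, else frameshift). Splice
donor/acceptor terms apply to the two intronic bases flanking each exon in
transcription order; UTR, intron and up/downstream (±5 kb) terms cover the
rest. Carrier frequency is `carriers / n_samples`, where a carrier is any
sample with ≥1 alternate allele and `./.` counts as non-carrier.

Cross-referencing is keyed strictly by the naked genomic position
(chromosome, position, reference base, alternate base): the key type cannot
hold sample identifiers, genotypes or INFO fields, so nothing sensitive can
reach an annotation backend even in principle.

Every consequence call is cross-checked in the test suite against an
independent brute-force oracle that rebuilds the full mutant CDS and
translates both proteins, and the interval index against a linear scan.

## Worked example

Everything below is generated — no downloads. From Python:

```python
import tempfile
from varlollipop import FixtureSpec, VariantFilter, generate_bundle, run_pipeline

tmp = tempfile.mkdtemp()
bundle = generate_bundle(FixtureSpec(seed=1), tmp)   # toy genome + VCF + tables
res = run_pipeline(
    bundle.vcf, bundle.gff3, bundle.fasta, bundle.annotation_dir,
    gene_selector="TOY1",
    variant_filter=VariantFilter(
        allowed_consequences=frozenset({"missense_variant", "stop_gained"}),
        gnomad_af_max=0.01),
    out_dir=tmp + "/out", domains_path=bundle.domains_tsv)
print(res.variants_annotated, res.variants_passing)
```

prints `10 2`: gene TOY1 carries 10 variants, of which 2 are missense or
stop-gained with population frequency below 1 % (or absent from the
frequency table). The output directory holds the gene list, the lollipop
SVG (one lollipop per passing variant; stem height = carrier frequency) and
the variant table with one zygosity column per sample.

The same flow from the shell:

```bash
varlollipop fixtures --seed 1 --out-dir bundle
varlollipop genes bundle/variants.vcf --gff3 bundle/genes.gff3 --fasta bundle/genome.fa
# gene_id  symbol  variant_count  carrier_sample_count
# G001     TOY1    10             5
# G002     TOY2    10             5
varlollipop plot bundle/variants.vcf --gff3 bundle/genes.gff3 \
    --fasta bundle/genome.fa --annotations bundle/annotations \
    --domains bundle/domains.tsv --gene TOY1 \
    --consequence missense_variant --consequence stop_gained --out-dir out
# read=20 genes=2 annotated=10 passing=3
```

Annotation of TOY1's variants (from `examples/03_annotate_variants.py`):

```
TOY1 canonical transcript: G001.t1 (43 aa, strand +)
  chrT:216 A>G  start_lost               freq=0.40
  chrT:234 A>T  missense_variant  p.T7S  freq=0.40
  chrT:386 C>T  synonymous_variant       freq=0.20
  chrT:389 C>G  splice_donor_variant     freq=0.40
  ...
```

`p.T7S` is the protein HGVS of a missense change at residue 7; `freq` is
the fraction of the five VCF samples carrying the variant. The
`examples/` directory has one short script per capability (parsing,
gene listing, annotation, filtering + plotting, bookmarks).

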