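# Methods

## Scope and data model

The pipeline's atom is the normalized bi-allelic variant: chromosome,
1-based position, uppercase reference and alternate DNA alleles, and one
genotype per VCF sample. Multi-allelic rows are expanded on parse, one
record per ALT allele, with genotype indices remapped so the retained ALT
is 1 and all other ALTs become missing alleles; this conserves the total
count of non-reference allele calls across the expansion (a property the
suite checks with random genotypes). Symbolic ALTs (`<DEL>`, `*`,
breakends) are outside the exome SNV/indel focus and are dropped with a
warning. Positions are 1-based inclusive everywhere in the public API,
matching both VCF and GFF3; the interval index converts to half-open
0-based internally and never exposes that form.

Assembly detection scans header meta lines in the order `##reference`,
`##assembly`, contig attributes, first match wins, with `hg19`/`hg38`
mapped to GRCh37/GRCh38. A file identifying no assembly is labelled
`unknown` rather than rejected, and the CLI accepts an override; the choice
of which line "identifies" the assembly is this package's convention since
VCF itself does not mandate one.

## Gene models and translation

Gene models are Ensembl-flavoured GFF3 (gene → mRNA → exon/CDS via
`Parent`), parsed with gffutils into in-memory models; the genome is plain
FASTA via Biopython. A transcript is *translatable* when its spliced CDS —
concatenated CDS segments, reverse-complemented on the minus strand —
starts with ATG, ends with a stop codon, has length divisible by three and
no internal stop. Non-translatable transcripts stay in the gene list (they
can carry variants) but cannot be plotted. The canonical transcript is the
one flagged canonical (`tag=Ensembl_canonical`) when exactly one is; else
the longest CDS; ties broken by lexicographically smallest transcript id,
so the choice is deterministic.

Protein domains/features come from a sidecar TSV
(`transcript_id, label, category, aa_start, aa_end, source`) standing in
for domain databases; coordinates are validated against the protein length
at plot time.

## Consequence calls

A coding SNV is classified on its single affected codon: slice the codon
from the spliced CDS, substitute the (strand-complemented) alternate base,
translate both codons. Precedence when several labels could apply:
synonymous, then stop_gained, stop_lost, start_lost, missense. The order of
stop_gained before start_lost is immaterial for SNVs — no single
substitution turns ATG into a stop codon — but is fixed for definiteness
and mirrored exactly in the oracle. Splice terms are reserved for the two
intronic bases flanking an exon in transcription order (donor after, acceptor
before); a coding base near a junction stays CDS-classified. Variants
outside the transcript span but within 5 kb get upstream/downstream terms
relative to the strand. The reference allele is checked against the genome
and a mismatch is an error, since it indicates an assembly disagreement
rather than a variant.

Indels follow the VCF anchor-base convention: the first changed base
(anchor + 1 when REF and ALT share their first base) selects the region,
and in CDS the length difference decides frameshift vs in-frame. MNVs
confined to one codon are treated as a single codon substitution;
multi-codon MNVs fall back to missense. Finer splice-region subtypes,
NMD prediction and phase-aware effects are out of scope.

The engine is held to an independent brute-force oracle — rebuild the full
mutant CDS, translate both proteins, classify per changed residue — for
every possible SNV at every CDS position of the generated genes on both
strands (≈1,000 substitutions at the default fixture size), plus an
enumeration oracle for region labels. The fixture generator stamps its
ground-truth sidecar with the oracle, never with the engine, so end-to-end
agreement is a real check and not a tautology.

## Cross-referencing and privacy

The only join key is the naked genomic position: chromosome (with any
`chr` prefix stripped on both sides), position, reference and alternate
base. The key is a frozen dataclass with exactly those four fields, so
sample names, genotypes and INFO text are excluded by construction; tests
serialize every fixture key and assert mechanically that no sample
identifier or genotype string appears. Matching is allele-specific and
exact; a variant absent from a table is reported as absent, never as
zero frequency — whether absence passes a frequency filter is the filter's
explicit, configurable decision (default: pass). Annotation tables are one
TSV per database, hash-indexed in memory; they are toy-scale stand-ins for
locally installed population/identifier/clinical/somatic databases, and
real-database adapters are deliberately out of scope.

## Filtering

Variant and gene filters are pure conjunctions of their active criteria,
giving three algebraic guarantees the suite tests on random inputs:
anti-monotonicity (adding a criterion never grows the result), idempotence,
and empty-filter identity. "Clinical prediction" means membership in a set
of clinical-significance classes; "pathogenicity score" means SIFT ≤
threshold or PolyPhen ≥ threshold — either suffices when both are set,
because the two predictors estimate the same property with opposite scales
(SIFT deleterious-low, PolyPhen deleterious-high). Missing scores pass by
default (configurable) so sparse annotation does not silently hide
variants. A custom keep-set, when present, is applied as a final
intersection. Gene-level prioritization supports a minimum variant count, a
minimum consequence severity (using a fixed severity ranking with nonsense/
frameshift/splice at the top), symbol selection, and GO/HPO term matching.

## Rendering

The plot is computed in two pure stages: `layout_plot` produces a
resolution-independent PlotSpec (backbone scaled in amino acids, domain
boxes, one lollipop per variant), `render_svg` serializes it. Stem height
is linear in carrier frequency between 18 and 120 px; co-located variants
fan horizontally by a fixed 9 px step around their shared residue tick.
Non-coding variants are anchored to the nearest coding residue and drawn
hollow — the anchoring rule is this package's choice, as is the default
colour palette (both configurable via the style mapping). Four badges per
lollipop mark presence in the population/identifier/clinical/somatic
tables. Output is deterministic to the byte: no timestamps, no generated
ids, so repeated runs and the conservation checks (lollipop count = table
rows = filtered variants) are exact. PNG export draws the same PlotSpec
with matplotlib at a configurable DPI; SVG remains the canonical output.

## Bookmarks

Bookmarks serialize per-gene view state (transcript, shown features, the
active variant filter, hand-picked keys) as versioned JSON with stable key
order. Loading requires a matching major schema version, warns on a newer
minor version and on unknown keys, and round-trips entries exactly
(timestamp aside). The schema is package-specific and documented by the
dataclasses.

## Synthetic data

The fixture generator emulates the study conditions at desk scale: by
default 2 protein-coding genes (one per strand, 2–3 exons, CDS of 40–70
codons, UTRs of 6–15 nt, introns of 30–80 nt) on one toy contig, 5 samples,
and 10 variants per gene split 60 % coding / 15 % UTR / 15 % intron /
10 % splice with 15 % of coding variants planted as 1–3 nt indels —
proportions chosen to exercise every consequence path while keeping the
exhaustive SNV×oracle sweep in the hundreds of substitutions. Coding
sequences are built from non-stop codons between a forced ATG and stop, so
every generated transcript is translatable by construction. Annotation
tables cover 25–60 % of planted variants per database so absence paths are
always exercised. Everything derives from one seeded `random.Random`; the
same spec yields a byte-identical bundle.

What the generator does not emulate — realistic exome size, human
allele-frequency spectra, sequencing artefacts, multi-transcript genes,
overlapping genes — bounds what passing tests show: they demonstrate the
correctness of the coordinate arithmetic, classification logic, joins,
filter algebra and rendering invariants, not performance or robustness on
production-scale human exomes.

## Numerical and degenerate-input choices

Carrier zygosity: heterozygous when exactly one allele index is 1,
homozygous when at least two alleles are called and all equal 1; a sample
with `1/.` counts as a het carrier. QUAL and non-GT FORMAT fields are
carried as opaque text. Empty VCF bodies, genes without variants, filters
matching nothing and plots with zero lollipops are all valid, producing
empty-but-well-formed outputs. Problem sizes in the test suite (2–4 genes,
≤ 1,000 index queries, 100 random filter pairs, 25 bookmark states) were
chosen as the smallest sets that exercise every code path and both strands.
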