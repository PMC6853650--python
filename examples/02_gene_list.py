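"""Find the genes carrying variants via the interval index.

Loads gene models from GFF3 + FASTA, builds the per-chromosome interval
tree, and lists each gene hit by at least one VCF record with its distinct
variant count and the number of samples carrying any of them.
"""

import tempfile

from varlollipop import (
    FixtureSpec,
    build_index,
    generate_bundle,
    genes_with_variants,
    load_gene_models,
    parse_vcf,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_bundle(FixtureSpec(seed=1), tmp)
    genes, genome = load_gene_models(bundle.gff3, bundle.fasta)
    index = build_index(genes)
    _, records = parse_vcf(bundle.vcf)

    print("gene_id  symbol  variants  carrier_samples")
    for hit in genes_with_variants(index, list(records)):
        print(f"{hit.gene_id}   {hit.symbol}    {hit.variant_count}"
              f"        {hit.carrier_sample_count}")

# Each row is one gene overlapped by >=1 variant; variant counts are
# distinct (pos, ref, alt) sites within the gene span, and carrier_samples
# counts the samples with at least one alternate allele in that gene.
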