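"""Cross-reference, filter, and draw the protein lollipop diagram.

Runs the whole batch pipeline twice on one gene — once unfiltered, once
keeping only missense and stop-gained variants rarer than 1% in the local
population table — and writes the SVG plus the zygosity table each time.
"""

import tempfile

from varlollipop import FixtureSpec, VariantFilter, generate_bundle, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_bundle(FixtureSpec(seed=1), tmp)

    res_all = run_pipeline(
        bundle.vcf, bundle.gff3, bundle.fasta, bundle.annotation_dir,
        gene_selector="TOY1", out_dir=tmp + "/all",
        domains_path=bundle.domains_tsv,
    )
    print(f"unfiltered: {res_all.variants_annotated} annotated, "
          f"{res_all.variants_passing} plotted -> {res_all.outputs['svg']}")

    rare_damaging = VariantFilter(
        allowed_consequences=frozenset({"missense_variant", "stop_gained"}),
        gnomad_af_max=0.01,
    )
    res_filt = run_pipeline(
        bundle.vcf, bundle.gff3, bundle.fasta, bundle.annotation_dir,
        gene_selector="TOY1", variant_filter=rare_damaging,
        out_dir=tmp + "/filtered", domains_path=bundle.domains_tsv,
    )
    print(f"rare damaging: {res_filt.variants_passing} of "
          f"{res_filt.variants_annotated} variants pass the filter")

# The SVG contains one lollipop per passing variant: stem height encodes
# carrier frequency, head colour the consequence class, and the badge row
# presence in the population/identifier/clinical/somatic tables.
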