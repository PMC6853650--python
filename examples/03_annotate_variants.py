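"""Compute transcript consequences and protein changes for one gene.

Annotates every variant inside the first gene's canonical transcript:
Sequence Ontology term, protein position, amino-acid change and carrier
frequency among the VCF samples.
"""

import tempfile

from varlollipop import FixtureSpec, generate_bundle, parse_vcf, select_canonical
from varlollipop.consequence import annotate_all

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_bundle(FixtureSpec(seed=1), tmp)
    gene = bundle.genes[0]
    transcript = select_canonical(gene)
    _, records = parse_vcf(bundle.vcf)

    print(f"{gene.symbol} canonical transcript: {transcript.transcript_id} "
          f"({transcript.protein_length} aa, strand {transcript.strand})")
    for av in annotate_all(list(records), transcript, bundle.genome):
        v = av.variant
        print(f"  {v.chrom}:{v.pos} {v.ref_allele}>{v.alt_allele}  "
              f"{av.consequence_term:24s} {av.hgvs_p or '':10s} "
              f"freq={av.carrier_frequency:.2f}")

# Coding SNVs get a protein HGVS (p.E3* style); UTR/intron/splice variants
# get their region term; carrier frequency is carriers / total samples.
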