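"""Bookmarks, pipeline orchestration and run summaries.

A bookmark is a small versioned JSON document recording, per gene, which
transcript and protein features were shown and which variant filter (plus
any custom kept set) was active — enough to reproduce a view later.  The
pipeline function ties the stages together for batch use: parse + validate
the VCF, index the gene models, annotate the selected gene's variants,
cross-reference, filter, and write the gene list, variant table and SVG/PNG.
"""

from __future__ import annotations

import difflib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

from . import consequence, crossref, filters, gene_model, render, vcf_io
from .crossref import CrossRefKey
from .filters import VariantFilter

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


class BookmarkError(Exception):
    pass


class PipelineError(Exception):
    pass


@dataclass
class BookmarkEntry:
    gene_id: str
    transcript_id: str
    shown_features: list[str] = field(default_factory=list)
    variant_filter: VariantFilter = field(default_factory=VariantFilter)
    custom_keep: list[CrossRefKey] = field(default_factory=list)


@dataclass
class Bookmark:
    schema_version: str = SCHEMA_VERSION
    created: str = ""
    entries: list[BookmarkEntry] = field(default_factory=list)


def _filter_to_json(f: VariantFilter) -> dict:
    return {
        "allowed_consequences": sorted(f.allowed_consequences)
        if f.allowed_consequences is not None
        else None,
        "clinical_significance_in": sorted(f.clinical_significance_in)
        if f.clinical_significance_in is not None
        else None,
        "sift_max": f.sift_max,
        "polyphen_min": f.polyphen_min,
        "gnomad_af_max": f.gnomad_af_max,
        "absent_af_passes": f.absent_af_passes,
        "absent_score_passes": f.absent_score_passes,
    }


def _filter_from_json(d: dict) -> VariantFilter:
    return VariantFilter(
        allowed_consequences=frozenset(d["allowed_consequences"])
        if d.get("allowed_consequences") is not None
        else None,
        clinical_significance_in=frozenset(d["clinical_significance_in"])
        if d.get("clinical_significance_in") is not None
        else None,
        sift_max=d.get("sift_max"),
        polyphen_min=d.get("polyphen_min"),
        gnomad_af_max=d.get("gnomad_af_max"),
        absent_af_passes=d.get("absent_af_passes", True),
        absent_score_passes=d.get("absent_score_passes", True),
    )


def save_bookmark(bookmark: Bookmark) -> str:
    """Serialize a bookmark to JSON text (keys sorted, stable)."""
    doc = {
        "schema_version": bookmark.schema_version,
        "created": bookmark.created
        or datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
        "entries": [
            {
                "gene_id": e.gene_id,
                "transcript_id": e.transcript_id,
                "shown_features": list(e.shown_features),
                "variant_filter": _filter_to_json(e.variant_filter),
                "custom_keep": [
                    [k.chrom, k.pos, k.ref_allele, k.alt_allele]
                    for k in e.custom_keep
                ],
            }
            for e in bookmark.entries
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def load_bookmark(text: str) -> Bookmark:
    """Parse bookmark JSON; round-trips entries exactly (timestamp aside).

    The major schema version must match; a newer minor version loads with a
    warning.  Unknown extra keys are ignored with a warning.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BookmarkError(
            f"malformed bookmark JSON at line {exc.lineno} col {exc.colno}: {exc.msg}"
        ) from exc
    if "schema_version" not in doc:
        raise BookmarkError("bookmark lacks schema_version")
    version = str(doc["schema_version"])
    major = version.split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise BookmarkError(
            f"bookmark schema {version} incompatible with {SCHEMA_VERSION}"
        )
    if version != SCHEMA_VERSION:
        logger.warning(
            "bookmark schema %s newer than %s; loading anyway", version, SCHEMA_VERSION
        )
    known = {"schema_version", "created", "entries"}
    for key in set(doc) - known:
        logger.warning("bookmark: unknown key %r ignored", key)
    entries = []
    for e in doc.get("entries", []):
        entries.append(
            BookmarkEntry(
                gene_id=e["gene_id"],
                transcript_id=e["transcript_id"],
                shown_features=list(e.get("shown_features", [])),
                variant_filter=_filter_from_json(e.get("variant_filter", {})),
                custom_keep=[
                    CrossRefKey(chrom=k[0], pos=int(k[1]), ref_allele=k[2], alt_allele=k[3])
                    for k in e.get("custom_keep", [])
                ],
            )
        )
    return Bookmark(schema_version=version, created=doc.get("created", ""), entries=entries)


@dataclass
class PipelineResult:
    records_read: int
    genes_hit: int
    variants_annotated: int
    variants_passing: int
    outputs: dict[str, str] = field(default_factory=dict)
    issues: list = field(default_factory=list)


def run_pipeline(
    vcf_path: str,
    gff3_path: str,
    fasta_path: str,
    annotation_dir: str | None,
    gene_selector: str,
    variant_filter: VariantFilter | None = None,
    out_dir: str = ".",
    domains_path: str | None = None,
    write_png: bool = False,
) -> PipelineResult:
    """Batch run: VCF -> gene list, annotated variant table and lollipop SVG.

    *gene_selector* is a gene symbol or gene id; an unknown selector raises
    with the nearest symbol matches listed.  The log records counts at each
    stage; read >= in-gene >= annotated >= passing always holds.
    """
    for path, label in ((vcf_path, "VCF"), (gff3_path, "GFF3"), (fasta_path, "FASTA")):
        if not os.path.exists(path):
            raise PipelineError(f"{label} file not found: {path}")
    variant_filter = variant_filter or VariantFilter()
    os.makedirs(out_dir, exist_ok=True)

    genes, genome = gene_model.load_gene_models(gff3_path, fasta_path)
    index = gene_model.build_index(genes)

    issues: list[vcf_io.ValidationIssue] = []
    header, rec_iter = vcf_io.parse_vcf(vcf_path, issues=issues)
    records = list(rec_iter)
    issues += vcf_io.validate(header, records, contig_names=genome.contig_names)
    fatal = [i for i in issues if i.severity == "error"]
    if fatal:
        logger.warning("%d validation errors (first: %s)", len(fatal), fatal[0].message)
    logger.info(
        "assembly %s; %d records from %d samples",
        header.assembly_label,
        len(records),
        len(header.sample_names),
    )

    hits = gene_model.genes_with_variants(index, records)
    gene_list_path = os.path.join(out_dir, "gene_list.tsv")
    with open(gene_list_path, "w") as fh:
        fh.write("gene_id\tsymbol\tvariant_count\tcarrier_sample_count\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.symbol}\t{h.variant_count}\t{h.carrier_sample_count}\n")

    gene = index.by_symbol(gene_selector)
    if gene is None:
        try:
            gene = index.gene(gene_selector)
        except KeyError:
            near = difflib.get_close_matches(gene_selector, index.symbols(), n=3)
            hint = f"; did you mean {', '.join(near)}?" if near else ""
            raise PipelineError(f"unknown gene {gene_selector!r}{hint}")
    transcript = gene_model.select_canonical(gene)

    lo, hi = transcript.span
    in_gene = [
        r for r in records if r.chrom == transcript.chrom and lo <= r.pos <= hi
    ]
    annotated = consequence.annotate_all(in_gene, transcript, genome)

    store = (
        crossref.AnnotationStore.load(annotation_dir)
        if annotation_dir
        else crossref.AnnotationStore()
    )
    xrefs = crossref.lookup_all([a.variant for a in annotated], store)
    passing = filters.filter_variants(annotated, xrefs, variant_filter)

    features = []
    if domains_path and os.path.exists(domains_path):
        features = [
            f
            for f in gene_model.load_protein_features(domains_path)
            if f.transcript_id == transcript.transcript_id
        ]

    spec = render.layout_plot(transcript, features, passing, xrefs)
    svg_path = os.path.join(out_dir, f"{gene.symbol}.svg")
    with open(svg_path, "w") as fh:
        fh.write(render.render_svg(spec))
    outputs = {"gene_list": gene_list_path, "svg": svg_path}
    if write_png:
        png_path = os.path.join(out_dir, f"{gene.symbol}.png")
        render.render_png(spec, png_path)
        outputs["png"] = png_path

    _, table_text = render.export_table(passing, xrefs, header.sample_names)
    table_path = os.path.join(out_dir, f"{gene.symbol}_variants.tsv")
    with open(table_path, "w") as fh:
        fh.write(table_text)
    outputs["table"] = table_path

    logger.info(
        "records read=%d genes hit=%d annotated=%d passing=%d",
        len(records),
        len(hits),
        len(annotated),
        len(passing),
    )
    return PipelineResult(
        records_read=len(records),
        genes_hit=len(hits),
        variants_annotated=len(annotated),
        variants_passing=len(passing),
        outputs=outputs,
        issues=issues,
    )
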