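"""Protein lollipop diagram (SVG, optional PNG) and the variant table.

The diagram shows the primary structure of one protein as a horizontal
backbone scaled in amino acids, domain/feature boxes over it, and one
lollipop per variant: the stem height grows linearly with carrier frequency
among the VCF samples, the head colour encodes the consequence class, and a
row of four small badges under the axis marks presence in the population,
identifier, clinical and somatic databases.  Variants without a protein
position (UTR / intron / splice) are anchored to the nearest coding residue
and drawn hollow.

Layout and serialization are pure functions: the same inputs produce
byte-identical SVG (no timestamps, no random ids), which the test suite
relies on.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .consequence import AnnotatedVariant
from .crossref import DATABASES, CrossRefKey, CrossRefRecord, make_key
from .gene_model import ProteinFeature, Transcript

#: consequence class -> lollipop head colour
DEFAULT_STYLE: dict[str, object] = {
    "width": 900,
    "margin": 50,
    "backbone_y": 230,
    "backbone_height": 12,
    "stem_min_px": 18,
    "stem_max_px": 120,
    "head_radius": 7,
    "fan_offset_px": 9,
    "badge_size": 6,
    "colors": {
        "stop_gained": "#c0392b",
        "frameshift_variant": "#8e44ad",
        "stop_lost": "#d35400",
        "start_lost": "#d35400",
        "splice_donor_variant": "#16a085",
        "splice_acceptor_variant": "#16a085",
        "inframe_insertion": "#2980b9",
        "inframe_deletion": "#2980b9",
        "missense_variant": "#27ae60",
        "synonymous_variant": "#7f8c8d",
        "default": "#95a5a6",
    },
    "domain_color": "#f39c12",
    "feature_color": "#3498db",
}


class RenderError(Exception):
    pass


@dataclass(frozen=True)
class Lollipop:
    x: float
    stem_top_y: float
    anchor_aa: int
    color: str
    hollow: bool
    consequence: str
    label: str
    badges: tuple[bool, bool, bool, bool]  # gnomad, dbsnp, clinvar, cosmic


@dataclass(frozen=True)
class DomainBox:
    label: str
    x0: float
    x1: float
    color: str


@dataclass
class PlotSpec:
    transcript_id: str
    protein_length: int
    width: int
    height: int
    margin: int
    backbone_y: int
    backbone_height: int
    domains: list[DomainBox] = field(default_factory=list)
    lollipops: list[Lollipop] = field(default_factory=list)
    legend: list[tuple[str, str]] = field(default_factory=list)  # (label, color)

    def x_of_aa(self, aa: float) -> float:
        scale = (self.width - 2 * self.margin) / self.protein_length
        return self.margin + (aa - 0.5) * scale


def nearest_protein_anchor(av: AnnotatedVariant, transcript: Transcript) -> int:
    """Protein residue nearest (in genomic distance) to a non-coding variant."""
    positions = transcript.cds_positions()
    pos = av.variant.pos
    best_i = min(range(len(positions)), key=lambda i: abs(positions[i] - pos))
    return best_i // 3 + 1


def layout_plot(
    transcript: Transcript,
    features: Sequence[ProteinFeature],
    variants: Sequence[AnnotatedVariant],
    xrefs: Mapping[CrossRefKey, CrossRefRecord],
    style: dict | None = None,
) -> PlotSpec:
    """Deterministic geometry for the lollipop diagram.

    Stem height is linear in carrier frequency between the configured
    min/max pixels; co-located variants fan horizontally by a fixed offset
    while staying anchored to the same residue tick.
    """
    st = dict(DEFAULT_STYLE)
    if style:
        st.update(style)
    plen = transcript.protein_length
    if plen is None:
        raise RenderError(f"{transcript.transcript_id} has no protein to draw")
    spec = PlotSpec(
        transcript_id=transcript.transcript_id,
        protein_length=plen,
        width=int(st["width"]),
        height=int(st["backbone_y"]) + 90,
        margin=int(st["margin"]),
        backbone_y=int(st["backbone_y"]),
        backbone_height=int(st["backbone_height"]),
    )
    for f in features:
        if f.aa_end > plen or f.aa_start < 1:
            raise RenderError(
                f"feature {f.label!r} ({f.aa_start}-{f.aa_end}) outside protein 1-{plen}"
            )
        color = st["domain_color"] if f.category == "domain" else st["feature_color"]
        spec.domains.append(
            DomainBox(
                label=f.label,
                x0=spec.x_of_aa(f.aa_start),
                x1=spec.x_of_aa(f.aa_end),
                color=color,
            )
        )

    colors: dict = st["colors"]  # type: ignore[assignment]
    by_anchor: dict[int, list[AnnotatedVariant]] = {}
    anchored: list[tuple[AnnotatedVariant, int, bool]] = []
    for av in variants:
        if av.protein_pos is not None and 1 <= av.protein_pos <= plen:
            anchor, hollow = av.protein_pos, False
        elif av.protein_pos is not None:
            anchor, hollow = min(max(av.protein_pos, 1), plen), False
        else:
            anchor, hollow = nearest_protein_anchor(av, transcript), True
        anchored.append((av, anchor, hollow))
        by_anchor.setdefault(anchor, []).append(av)

    smin, smax = float(st["stem_min_px"]), float(st["stem_max_px"])
    seen_at_anchor: dict[int, int] = {}
    used_terms: list[str] = []
    for av, anchor, hollow in anchored:
        k = seen_at_anchor.get(anchor, 0)
        seen_at_anchor[anchor] = k + 1
        # fan: 0, +d, -d, +2d, ... around the anchor tick
        step = (k + 1) // 2 * float(st["fan_offset_px"])
        dx = step if k % 2 == 1 else -step if k else 0.0
        stem = smin + av.carrier_frequency * (smax - smin)
        xref = xrefs.get(make_key(av.variant), CrossRefRecord())
        label = av.hgvs_p or f"{av.variant.ref_allele}>{av.variant.alt_allele}"
        spec.lollipops.append(
            Lollipop(
                x=spec.x_of_aa(anchor) + dx,
                stem_top_y=spec.backbone_y - stem,
                anchor_aa=anchor,
                color=colors.get(av.consequence_term, colors["default"]),
                hollow=hollow,
                consequence=av.consequence_term,
                label=label,
                badges=tuple(xref.present_in(db) for db in DATABASES),
            )
        )
        if av.consequence_term not in used_terms:
            used_terms.append(av.consequence_term)
    spec.legend = [
        (term, colors.get(term, colors["default"])) for term in sorted(used_terms)
    ]
    return spec


def render_svg(spec: PlotSpec) -> str:
    """Serialize a PlotSpec to standalone SVG 1.1 text.

    Each lollipop, domain box and legend entry becomes one identifiable
    ``<g>`` element (class attributes ``lollipop`` / ``domain`` /
    ``legend-entry``), so counts can be asserted on the document.
    """
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": str(spec.width),
            "height": str(spec.height),
            "viewBox": f"0 0 {spec.width} {spec.height}",
        },
    )
    title = ET.SubElement(svg, "text", {"x": str(spec.margin), "y": "24",
                                        "font-size": "16", "font-family": "sans-serif"})
    title.text = f"{spec.transcript_id} ({spec.protein_length} aa)"

    y = spec.backbone_y
    ET.SubElement(
        svg,
        "rect",
        {
            "class": "backbone",
            "x": f"{spec.x_of_aa(0.5):.2f}",
            "y": f"{y - spec.backbone_height / 2:.2f}",
            "width": f"{spec.x_of_aa(spec.protein_length + 0.5) - spec.x_of_aa(0.5):.2f}",
            "height": str(spec.backbone_height),
            "fill": "#bdc3c7",
        },
    )
    # axis ticks at 1 and protein_length
    for aa in (1, spec.protein_length):
        tx = spec.x_of_aa(aa)
        t = ET.SubElement(svg, "text", {"x": f"{tx:.2f}", "y": str(y + 28),
                                        "font-size": "10", "text-anchor": "middle",
                                        "font-family": "sans-serif"})
        t.text = str(aa)

    for d in spec.domains:
        g = ET.SubElement(svg, "g", {"class": "domain"})
        ET.SubElement(
            g,
            "rect",
            {
                "x": f"{d.x0:.2f}",
                "y": f"{y - spec.backbone_height:.2f}",
                "width": f"{max(d.x1 - d.x0, 2.0):.2f}",
                "height": str(2 * spec.backbone_height),
                "fill": d.color,
                "stroke": "#7f6000",
                "rx": "3",
            },
        )
        t = ET.SubElement(g, "text", {"x": f"{(d.x0 + d.x1) / 2:.2f}",
                                      "y": f"{y + spec.backbone_height + 12:.2f}",
                                      "font-size": "9", "text-anchor": "middle",
                                      "font-family": "sans-serif"})
        t.text = d.label

    bs = 6.0
    for lp in spec.lollipops:
        g = ET.SubElement(svg, "g", {"class": "lollipop"})
        ET.SubElement(
            g,
            "line",
            {
                "x1": f"{lp.x:.2f}",
                "y1": f"{y - spec.backbone_height / 2:.2f}",
                "x2": f"{lp.x:.2f}",
                "y2": f"{lp.stem_top_y:.2f}",
                "stroke": "#2c3e50",
                "stroke-width": "1.2",
            },
        )
        ET.SubElement(
            g,
            "circle",
            {
                "cx": f"{lp.x:.2f}",
                "cy": f"{lp.stem_top_y:.2f}",
                "r": "7",
                "fill": "none" if lp.hollow else lp.color,
                "stroke": lp.color,
                "stroke-width": "2",
            },
        )
        t = ET.SubElement(g, "text", {"x": f"{lp.x:.2f}",
                                      "y": f"{lp.stem_top_y - 10:.2f}",
                                      "font-size": "8", "text-anchor": "middle",
                                      "font-family": "sans-serif"})
        t.text = lp.label
        for i, present in enumerate(lp.badges):
            ET.SubElement(
                g,
                "rect",
                {
                    "class": f"badge badge-{DATABASES[i]}",
                    "x": f"{lp.x - 2 * bs + i * bs:.2f}",
                    "y": f"{y + 34:.2f}",
                    "width": f"{bs - 1:.0f}",
                    "height": f"{bs - 1:.0f}",
                    "fill": "#2c3e50" if present else "#ecf0f1",
                    "stroke": "#95a5a6",
                    "stroke-width": "0.5",
                },
            )

    ly = y + 56
    for i, (label, color) in enumerate(spec.legend):
        g = ET.SubElement(svg, "g", {"class": "legend-entry"})
        x0 = spec.margin + (i % 4) * 200
        yy = ly + (i // 4) * 16
        ET.SubElement(g, "rect", {"x": str(x0), "y": str(yy), "width": "10",
                                  "height": "10", "fill": color})
        t = ET.SubElement(g, "text", {"x": str(x0 + 14), "y": str(yy + 9),
                                      "font-size": "10", "font-family": "sans-serif"})
        t.text = label

    return ET.tostring(svg, encoding="unicode")


def render_png(spec: PlotSpec, path: str, dpi: int = 150) -> None:
    """Optional raster export, drawn from the same PlotSpec with matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(spec.width / 100, spec.height / 100), dpi=dpi)
    ax.set_xlim(0, spec.width)
    ax.set_ylim(spec.height, 0)
    ax.axis("off")
    y = spec.backbone_y
    ax.add_patch(
        plt.Rectangle(
            (spec.x_of_aa(0.5), y - spec.backbone_height / 2),
            spec.x_of_aa(spec.protein_length + 0.5) - spec.x_of_aa(0.5),
            spec.backbone_height,
            color="#bdc3c7",
        )
    )
    for d in spec.domains:
        ax.add_patch(
            plt.Rectangle(
                (d.x0, y - spec.backbone_height),
                max(d.x1 - d.x0, 2.0),
                2 * spec.backbone_height,
                color=d.color,
            )
        )
    for lp in spec.lollipops:
        ax.plot([lp.x, lp.x], [y, lp.stem_top_y], color="#2c3e50", lw=1.2)
        face = "none" if lp.hollow else lp.color
        ax.scatter([lp.x], [lp.stem_top_y], s=60, facecolors=face, edgecolors=lp.color)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "hgvs_p",
    "protein_pos",
    "gnomad_af",
    "rsid",
    "clinvar_significance",
    "cosmic_id",
    "sift",
    "polyphen",
]


def export_table(
    variants: Sequence[AnnotatedVariant],
    xrefs: Mapping[CrossRefKey, CrossRefRecord],
    sample_names: Sequence[str],
    sep: str = "\t",
) -> tuple[pd.DataFrame, str]:
    """The downloadable variant table, one zygosity column per sample.

    Zygosity cells are ``het``/``hom`` for carriers and empty otherwise;
    sample columns follow VCF order after the fixed annotation columns.
    """
    rows = []
    for av in variants:
        xref = xrefs.get(make_key(av.variant), CrossRefRecord())
        zyg = dict(av.carrier_samples)
        row = {
            "chrom": av.variant.chrom,
            "pos": av.variant.pos,
            "ref": av.variant.ref_allele,
            "alt": av.variant.alt_allele,
            "consequence": av.consequence_term,
            "hgvs_p": av.hgvs_p or "",
            "protein_pos": av.protein_pos if av.protein_pos is not None else "",
            "gnomad_af": xref.gnomad_af if xref.gnomad_af is not None else "",
            "rsid": xref.rsid or "",
            "clinvar_significance": xref.clinvar_significance or "",
            "cosmic_id": xref.cosmic_id or "",
            "sift": xref.sift_score if xref.sift_score is not None else "",
            "polyphen": xref.polyphen_score if xref.polyphen_score is not None else "",
        }
        for name in sample_names:
            row[name] = zyg.get(name, "")
        rows.append(row)
    columns = TABLE_COLUMNS + list(sample_names)
    df = pd.DataFrame(rows, columns=columns)
    return df, df.to_csv(sep=sep, index=False)
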