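"""Joining variants to local knowledge tables through a privacy-preserving key.

The only datum that ever reaches the annotation store is the naked genomic
position — chromosome, position, reference and alternate base.  Sample
names, genotypes and user INFO fields are structurally absent from
:class:`CrossRefKey`, so the privacy boundary is enforced by the type, not
by discipline.

Tables are toy-scale TSV stand-ins for locally installed population
(gnomAD-style allele frequencies), identifier (dbSNP rsIDs), clinical
(ClinVar significance) and somatic (COSMIC ids) databases, plus SIFT /
PolyPhen score tables and a per-gene GO/HPO term table.  A variant absent
from a table is reported as absent — never as zero frequency.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping

import pandas as pd

from .vcf_io import VariantRecord

logger = logging.getLogger(__name__)

#: table file names expected inside an annotation directory
TABLE_FILES = {
    "gnomad": "gnomad.tsv",
    "dbsnp": "dbsnp.tsv",
    "clinvar": "clinvar.tsv",
    "cosmic": "cosmic.tsv",
    "scores": "scores.tsv",
}
TERMS_FILE = "terms.tsv"

DATABASES = ("gnomad", "dbsnp", "clinvar", "cosmic")


def _norm_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix so both sides of the join use one convention."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class CrossRefKey:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def serialize(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class CrossRefRecord:
    gnomad_af: float | None = None
    rsid: str | None = None
    clinvar_significance: str | None = None
    cosmic_id: str | None = None
    sift_score: float | None = None
    sift_class: str | None = None
    polyphen_score: float | None = None
    polyphen_class: str | None = None

    def present_in(self, database: str) -> bool:
        """Whether the key hit the named database (field present <=> hit)."""
        attr = {
            "gnomad": "gnomad_af",
            "dbsnp": "rsid",
            "clinvar": "clinvar_significance",
            "cosmic": "cosmic_id",
        }[database]
        return getattr(self, attr) is not None


EMPTY_RECORD = CrossRefRecord()


@dataclass(frozen=True)
class GeneTermSet:
    symbol: str
    go_terms: frozenset[str] = frozenset()
    hpo_terms: frozenset[str] = frozenset()


def make_key(variant: VariantRecord) -> CrossRefKey:
    """Project a variant to its naked genomic position.

    The key carries nothing but chrom/pos/ref/alt — two records differing
    only in genotypes yield equal keys.
    """
    return CrossRefKey(
        chrom=_norm_chrom(variant.chrom),
        pos=variant.pos,
        ref_allele=variant.ref_allele,
        alt_allele=variant.alt_allele,
    )


class AnnotationStore:
    """In-memory, hash-indexed annotation tables keyed by (chrom,pos,ref,alt)."""

    def __init__(self) -> None:
        self._tables: dict[str, dict[tuple, dict]] = {k: {} for k in TABLE_FILES}
        self._terms: dict[str, tuple[frozenset, frozenset]] = {}

    @classmethod
    def load(cls, directory: str) -> "AnnotationStore":
        """Load every table TSV found in *directory*; missing files are fine."""
        store = cls()
        for name, fname in TABLE_FILES.items():
            path = os.path.join(directory, fname)
            if os.path.exists(path):
                store._load_table(name, path)
        tpath = os.path.join(directory, TERMS_FILE)
        if os.path.exists(tpath):
            store._load_terms(tpath)
        return store

    def _load_table(self, name: str, path: str) -> None:
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"chrom", "pos", "ref", "alt"}
        if not required <= set(df.columns):
            logger.warning("%s: missing key columns; table ignored", path)
            return
        table = self._tables[name]
        for i, row in enumerate(df.to_dict("records")):
            try:
                key = (
                    _norm_chrom(str(row["chrom"])),
                    int(row["pos"]),
                    str(row["ref"]).upper(),
                    str(row["alt"]).upper(),
                )
            except (ValueError, TypeError) as exc:
                logger.warning("%s row %d malformed (%s); skipped", path, i + 2, exc)
                continue
            table[key] = row

    def _load_terms(self, path: str) -> None:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for symbol, sub in df.groupby("symbol"):
            go = frozenset(sub.loc[sub.ontology == "GO", "term_id"])
            hpo = frozenset(sub.loc[sub.ontology == "HPO", "term_id"])
            self._terms[symbol] = (go, hpo)

    def lookup(self, key: CrossRefKey) -> CrossRefRecord:
        """Exact-match join across all tables; misses yield absent fields."""
        k = (key.chrom, key.pos, key.ref_allele, key.alt_allele)
        g = self._tables["gnomad"].get(k)
        d = self._tables["dbsnp"].get(k)
        c = self._tables["clinvar"].get(k)
        m = self._tables["cosmic"].get(k)
        s = self._tables["scores"].get(k)
        return CrossRefRecord(
            gnomad_af=float(g["af"]) if g else None,
            rsid=d["rsid"] if d else None,
            clinvar_significance=c["significance"] if c else None,
            cosmic_id=m["cosmic_id"] if m else None,
            sift_score=float(s["sift_score"]) if s else None,
            sift_class=s["sift_class"] if s else None,
            polyphen_score=float(s["polyphen_score"]) if s else None,
            polyphen_class=s["polyphen_class"] if s else None,
        )

    def gene_terms(self, symbol: str) -> GeneTermSet:
        """GO/HPO term sets for a gene symbol (case-sensitive; may be empty)."""
        go, hpo = self._terms.get(symbol, (frozenset(), frozenset()))
        return GeneTermSet(symbol=symbol, go_terms=go, hpo_terms=hpo)


def lookup(key: CrossRefKey, store: AnnotationStore) -> CrossRefRecord:
    return store.lookup(key)


def gene_terms(symbol: str, store: AnnotationStore) -> GeneTermSet:
    return store.gene_terms(symbol)


def lookup_all(
    records: Iterable[VariantRecord], store: AnnotationStore
) -> dict[CrossRefKey, CrossRefRecord]:
    """Batch join: one (possibly all-absent) entry per distinct key."""
    out: dict[CrossRefKey, CrossRefRecord] = {}
    for rec in records:
        key = make_key(rec)
        if key not in out:
            out[key] = store.lookup(key)
    return out
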