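"""Variant-level filtering and gene-level prioritization.

Both filters are pure conjunctions: a variant (or gene) passes only if it
satisfies every *active* criterion, so adding a criterion can never grow the
result (anti-monotonicity), applying a filter twice equals once
(idempotence), and the empty filter is the identity.

Score semantics follow the predictors' conventions: SIFT is
deleterious-low (a variant passes ``sift_max`` when its score is <= the
threshold) and PolyPhen deleterious-high (passes ``polyphen_min`` when >=).
When both score thresholds are set, satisfying either suffices — they are
two predictors of the same property.  Variants lacking a score or a
population frequency pass those criteria by default, so sparsely annotated
data is not silently hidden; set ``absent_af_passes=False`` to treat absent
frequency as failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .consequence import SEVERITY_RANK, AnnotatedVariant
from .crossref import CrossRefKey, CrossRefRecord, GeneTermSet, make_key
from .gene_model import GeneHit


@dataclass(frozen=True)
class VariantFilter:
    allowed_consequences: frozenset[str] | None = None  # None = any
    clinical_significance_in: frozenset[str] | None = None
    sift_max: float | None = None
    polyphen_min: float | None = None
    gnomad_af_max: float | None = None
    absent_af_passes: bool = True
    absent_score_passes: bool = True
    custom_keep: frozenset[CrossRefKey] | None = None

    def __post_init__(self) -> None:
        for name in ("sift_max", "polyphen_min", "gnomad_af_max"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0,1], got {v}")

    def is_empty(self) -> bool:
        return (
            self.allowed_consequences is None
            and self.clinical_significance_in is None
            and self.sift_max is None
            and self.polyphen_min is None
            and self.gnomad_af_max is None
            and self.custom_keep is None
        )

    def passes(self, av: AnnotatedVariant, xref: CrossRefRecord) -> bool:
        if (
            self.allowed_consequences is not None
            and av.consequence_term not in self.allowed_consequences
        ):
            return False
        if self.clinical_significance_in is not None:
            if xref.clinvar_significance is None:
                return False
            if xref.clinvar_significance not in self.clinical_significance_in:
                return False
        if self.sift_max is not None or self.polyphen_min is not None:
            if not self._passes_scores(xref):
                return False
        if self.gnomad_af_max is not None:
            if xref.gnomad_af is None:
                if not self.absent_af_passes:
                    return False
            elif xref.gnomad_af > self.gnomad_af_max:
                return False
        if self.custom_keep is not None and make_key(av.variant) not in self.custom_keep:
            return False
        return True

    def _passes_scores(self, xref: CrossRefRecord) -> bool:
        checks = []
        if self.sift_max is not None:
            if xref.sift_score is None:
                checks.append(None)
            else:
                checks.append(xref.sift_score <= self.sift_max)
        if self.polyphen_min is not None:
            if xref.polyphen_score is None:
                checks.append(None)
            else:
                checks.append(xref.polyphen_score >= self.polyphen_min)
        concrete = [c for c in checks if c is not None]
        if not concrete:
            return self.absent_score_passes
        # two predictors of the same property: either satisfying suffices
        return any(concrete)


EMPTY_FILTER = VariantFilter()


def filter_variants(
    annotated: Sequence[AnnotatedVariant],
    xrefs: Mapping[CrossRefKey, CrossRefRecord],
    f: VariantFilter,
) -> list[AnnotatedVariant]:
    """Variants passing every active criterion, input order preserved."""
    out = []
    for av in annotated:
        xref = xrefs.get(make_key(av.variant), CrossRefRecord())
        if f.passes(av, xref):
            out.append(av)
    return out


@dataclass(frozen=True)
class GeneFilter:
    min_variants: int = 0
    required_consequence_severity_at_least: str | None = None
    symbols_in: frozenset[str] | None = None
    go_or_hpo_terms_any: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.min_variants < 0:
            raise ValueError("min_variants must be >= 0")


def filter_genes(
    hits: Sequence[GeneHit],
    annotations_by_gene: Mapping[str, Sequence[AnnotatedVariant]],
    term_sets: Mapping[str, GeneTermSet],
    g: GeneFilter,
) -> list[GeneHit]:
    """Gene prioritization: conjunction of the active gene-level criteria.

    The severity criterion keeps a gene when any of its variants has
    severity rank >= the stated term's rank.  Unknown symbols in
    ``symbols_in`` are ignored (they simply match nothing).
    """
    out = []
    min_rank = (
        SEVERITY_RANK[g.required_consequence_severity_at_least]
        if g.required_consequence_severity_at_least is not None
        else None
    )
    for hit in hits:
        if hit.variant_count < g.min_variants:
            continue
        if g.symbols_in is not None and hit.symbol not in g.symbols_in:
            continue
        if min_rank is not None:
            anns = annotations_by_gene.get(hit.gene_id, ())
            if not any(a.severity_rank >= min_rank for a in anns):
                continue
        if g.go_or_hpo_terms_any is not None:
            ts = term_sets.get(hit.symbol)
            terms = (ts.go_terms | ts.hpo_terms) if ts else frozenset()
            if not (terms & g.go_or_hpo_terms_any):
                continue
        out.append(hit)
    return out
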