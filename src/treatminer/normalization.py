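"""Entity normalisation (linking) and its summary statistics.

Recognised entity surfaces are linked to dictionary concept identifiers
by tiered flexible matching; the summaries quantify (a) how many
annotated entities were mapped to Concept IDs, per trait category where
applicable, and (b) how much of each dictionary the corpus actually
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .dictionaries import Dictionary, normalize_surface, strip_plural
from .model import Document, EntityAnnotation, ValidationError


@dataclass
class NormalizationResult:
    concept_id: Optional[str]
    tier: Optional[str]
    ambiguous: bool = False


@dataclass
class NormalizationSummary:
    """Mapping summary: of ``m`` annotated entities, ``k`` were linked."""

    kind: str
    m: int
    k: int
    percent_mapped: float
    per_category: dict[str, int]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.m):
            raise ValidationError(f"k={self.k} outside [0, m={self.m}]")


@dataclass
class CoverageSummary:
    """Coverage summary: of ``n`` dictionary terms, ``l`` were observed."""

    n: int
    l: int
    percent_covered: float

    def __post_init__(self) -> None:
        if not (0 <= self.l <= self.n):
            raise ValidationError(f"l={self.l} outside [0, n={self.n}]")


def _percent(numerator: int, denominator: int, precision: int) -> float:
    if denominator == 0:
        return 0.0
    value = 100.0 * numerator / denominator
    return round(value) if precision == 0 else round(value, precision)


def normalize_entity(
    entity: EntityAnnotation, dictionary: Dictionary
) -> NormalizationResult:
    """Link one entity surface to a concept id by tiered matching.

    Tiers, first hit wins: exact raw surface; case-folded; case-folded
    with whitespace collapsed; plural-stripped; all tiers consult
    synonyms as well as preferred terms.  An ambiguous hit within a tier
    resolves to the lexicographically smallest concept id and is flagged.
    """
    surface = entity.surface
    if not surface:
        return NormalizationResult(None, None)
    # tier 1: exact raw form
    hits = dictionary.exact_index.get(surface)
    if hits:
        return NormalizationResult(min(hits), "exact", len(hits) > 1)
    # tier 2: case-folded (whitespace untouched beyond outer strip)
    folded = surface.strip().casefold()
    hits = dictionary.surface_index.get(folded) if " " not in folded else None
    if hits:
        return NormalizationResult(min(hits), "casefold", len(hits) > 1)
    # tier 3: whitespace-collapsed case-folded
    key = normalize_surface(surface)
    hits = dictionary.surface_index.get(key)
    if hits:
        return NormalizationResult(min(hits), "whitespace", len(hits) > 1)
    # tier 4: plural-stripped
    words = key.split()
    if words:
        singular = strip_plural(words[-1])
        if singular is not None:
            hits = dictionary.surface_index.get(" ".join(words[:-1] + [singular]))
            if hits:
                return NormalizationResult(min(hits), "plural", len(hits) > 1)
    return NormalizationResult(None, None)


def normalize_document(
    doc: Document, taxa: Optional[Dictionary] = None, traits: Optional[Dictionary] = None
) -> Document:
    """Attach concept ids to a document's arthropod and trait entities."""
    by_type = {"arthropod": taxa, "trait": traits}
    linked = []
    for ann in doc.with_surfaces().annotations:
        dictionary = by_type.get(ann.etype)
        if dictionary is None or ann.concept_id is not None:
            linked.append(ann)
            continue
        result = normalize_entity(ann, dictionary)
        linked.append(replace(ann, concept_id=result.concept_id))
    return Document(doc.doc_id, doc.text, linked, list(doc.relations), doc.split_tag)


def summarize_normalization(
    entities: Sequence[EntityAnnotation],
    kind: str,
    dictionary: Optional[Dictionary] = None,
    precision: int = 1,
) -> NormalizationSummary:
    """Count linked entities (``k`` of ``m``) and their trait categories.

    Trait-category attribution requires the dictionary and happens only
    for successfully linked entities.  ``precision=0`` reports an integer
    percentage; the empty input reports 0% by convention.
    """
    m = len(entities)
    k = sum(1 for e in entities if e.concept_id is not None)
    per_category: dict[str, int] = {}
    if dictionary is not None:
        for e in entities:
            if e.concept_id is not None and e.concept_id in dictionary:
                cat = dictionary[e.concept_id].category
                per_category[cat] = per_category.get(cat, 0) + 1
    return NormalizationSummary(
        kind=kind, m=m, k=k, percent_mapped=_percent(k, m, precision),
        per_category=per_category,
    )


def dictionary_coverage(
    entities: Sequence[EntityAnnotation],
    dictionary: Dictionary,
    precision: int = 1,
) -> CoverageSummary:
    """How many distinct dictionary concepts the entities touched."""
    observed: set[str] = set()
    for e in entities:
        if e.concept_id is None:
            continue
        if e.concept_id not in dictionary:
            raise ValidationError(
                f"concept id {e.concept_id!r} not in the dictionary"
            )
        observed.add(e.concept_id)
    n = len(dictionary)
    return CoverageSummary(
        n=n, l=len(observed), percent_covered=_percent(len(observed), n, precision)
    )


def unique_surface_count(entities: Sequence[EntityAnnotation]) -> int:
    """Number of distinct case-folded entity surface forms."""
    return len({e.surface.casefold() for e in entities if e.surface})
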