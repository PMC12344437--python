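"""Corpus and annotation statistics.

Annotation densities per 1,000 characters per entity/relation type,
corpus-level totals, document-length quantiles and train/test split
bookkeeping.  Quantiles use numpy's linear-interpolation convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Document, ENTITY_TYPES

DENSITY_TYPES = ("arthropod", "trait", "value", "qualifier",
                 "hasTrait", "hasValue", "hasQualifier")


@dataclass
class DensityReport:
    doc_id: str
    length_chars: int
    counts: dict[str, int]
    density: dict[str, float]  # annotations per 1,000 characters


@dataclass
class CorpusSummary:
    n_docs: int
    entity_totals: dict[str, int]
    relation_totals: dict[str, int]
    total_entities: int
    total_relations: int
    length_median: float
    length_q1: float
    length_q3: float
    split_totals: dict[str, int] = field(default_factory=dict)
    train_test_ratio_percent: float = 0.0


def annotation_density(doc: Document) -> DensityReport:
    """Per-type annotation counts and densities per 1,000 characters."""
    if doc.length == 0:
        raise ValueError(f"{doc.doc_id}: zero-length document has no density")
    counts = {t: 0 for t in DENSITY_TYPES}
    for ann in doc.annotations:
        counts[ann.etype] += 1
    for rel in doc.relations:
        if rel.rtype in counts:
            counts[rel.rtype] += 1
    density = {t: 1000.0 * c / doc.length for t, c in counts.items()}
    return DensityReport(doc.doc_id, doc.length, counts, density)


def density_medians(docs: Sequence[Document]) -> dict[str, float]:
    """Median per-document density for each annotation type."""
    reports = [annotation_density(d) for d in docs if d.length > 0]
    return {
        t: float(np.median([r.density[t] for r in reports])) if reports else 0.0
        for t in DENSITY_TYPES
    }


def corpus_summary(docs: Sequence[Document]) -> CorpusSummary:
    """Corpus totals, length quartiles and split bookkeeping.

    The split ratio follows the train-vs-test convention
    ``100 * (TRAIN-GOLD annotations) / (TEST-GOLD annotations)``, where an
    annotation is an entity or a relation.
    """
    entity_totals = {t: 0 for t in ENTITY_TYPES}
    relation_totals: dict[str, int] = {}
    split_totals: dict[str, int] = {}
    for doc in docs:
        n_ann = len(doc.annotations) + len(doc.relations)
        if doc.split_tag:
            split_totals[doc.split_tag] = split_totals.get(doc.split_tag, 0) + n_ann
        for ann in doc.annotations:
            entity_totals[ann.etype] += 1
        for rel in doc.relations:
            relation_totals[rel.rtype] = relation_totals.get(rel.rtype, 0) + 1
    lengths = [d.length for d in docs]
    if lengths:
        q1, med, q3 = (float(q) for q in np.percentile(lengths, [25, 50, 75]))
    else:
        q1 = med = q3 = 0.0
    train = split_totals.get("TRAIN-GOLD", 0)
    test = split_totals.get("TEST-GOLD", 0)
    ratio = round(100.0 * train / test, 1) if test else 0.0
    return CorpusSummary(
        n_docs=len(docs),
        entity_totals=entity_totals,
        relation_totals=relation_totals,
        total_entities=sum(entity_totals.values()),
        total_relations=sum(relation_totals.values()),
        length_median=med,
        length_q1=q1,
        length_q3=q3,
        split_totals=split_totals,
        train_test_ratio_percent=ratio,
    )
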