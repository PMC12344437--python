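"""Scoring predicted against gold annotations.

Two entity evaluation modes are exposed:

* **strict** — a prediction counts only when character span and entity
  type both match a gold annotation exactly (one-to-one), scored on the
  annotation layer;
* **conll** — chunk-level exact match computed from IOB2 token label
  sequences with conlleval-style lenient repair (an orphan ``I-`` opens
  a chunk), so boundary choices inside tokens do not matter.

Relations are scored by exact match of head span, tail span and relation
type.  All reports carry per-type precision/recall/F1 with support,
plus macro (unweighted) and support-weighted aggregates.  Whenever a
denominator is zero the metric is 0 by convention.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .model import Document, EntityAnnotation, TokenLabelSequence, ValidationError
from .corpus_io import iob2_chunks

logger = logging.getLogger(__name__)

#: a relation resolved to spans: ((head_start, head_end), (tail_start, tail_end), rtype)
ResolvedRelation = tuple[tuple[int, int], tuple[int, int], str]


@dataclass
class TypeScore:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    per_type: dict[str, TypeScore]
    macro: TypeScore
    weighted: TypeScore
    mode: str

    def rounded(self, ndigits: int = 2) -> dict:
        """Report as nested dict with values rounded for display."""
        def r(s: TypeScore) -> dict:
            return {
                "P": round(s.precision, ndigits),
                "R": round(s.recall, ndigits),
                "F": round(s.f1, ndigits),
                "support": s.support,
            }
        return {
            "mode": self.mode,
            "per_type": {t: r(s) for t, s in sorted(self.per_type.items())},
            "macro": r(self.macro),
            "weighted": r(self.weighted),
        }


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0) or not (0.0 <= recall <= 1.0):
        raise ValueError(f"precision/recall outside [0, 1]: {precision}, {recall}")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        logger.debug("zero denominator; reporting 0 by convention")
        return 0.0
    return num / den


def _score(tp: int, n_pred: int, n_gold: int) -> TypeScore:
    p = _safe_div(tp, n_pred)
    r = _safe_div(tp, n_gold)
    return TypeScore(p, r, f1(p, r), n_gold)


def _aggregate(per_type: dict[str, TypeScore], mode: str) -> EvalReport:
    types = sorted(per_type)
    if not types:
        zero = TypeScore(0.0, 0.0, 0.0, 0)
        return EvalReport({}, zero, zero, mode)
    n = len(types)
    macro = TypeScore(
        sum(per_type[t].precision for t in types) / n,
        sum(per_type[t].recall for t in types) / n,
        sum(per_type[t].f1 for t in types) / n,
        sum(per_type[t].support for t in types),
    )
    total = sum(per_type[t].support for t in types)
    if total == 0:
        weighted = TypeScore(0.0, 0.0, 0.0, 0)
    else:
        weighted = TypeScore(
            sum(per_type[t].precision * per_type[t].support for t in types) / total,
            sum(per_type[t].recall * per_type[t].support for t in types) / total,
            sum(per_type[t].f1 * per_type[t].support for t in types) / total,
            total,
        )
    return EvalReport(per_type, macro, weighted, mode)


AnnotationsByDoc = Union[
    Mapping[str, Sequence[EntityAnnotation]], Sequence[EntityAnnotation]
]


def _as_mapping(annotations: AnnotationsByDoc) -> Mapping[str, Sequence[EntityAnnotation]]:
    if isinstance(annotations, Mapping):
        return annotations
    return {"_": annotations}


def strict_entity_eval(
    gold: AnnotationsByDoc, pred: AnnotationsByDoc
) -> EvalReport:
    """Exact span-and-type matching on the annotation layer.

    ``gold`` and ``pred`` are either flat annotation lists (one document)
    or mappings ``doc_id -> annotations``; predictions for a document
    absent from gold raise a consistency error.  Matching is one-to-one
    on the (span, type) multiset per document.
    """
    gold_map, pred_map = _as_mapping(gold), _as_mapping(pred)
    unknown = set(pred_map) - set(gold_map)
    if unknown:
        raise ValidationError(f"predictions reference unknown documents: {sorted(unknown)}")
    tp: Counter = Counter()
    n_gold: Counter = Counter()
    n_pred: Counter = Counter()
    for doc_id in gold_map:
        g = Counter((a.start, a.end, a.etype) for a in gold_map[doc_id])
        p = Counter((a.start, a.end, a.etype) for a in pred_map.get(doc_id, []))
        for key, count in (g & p).items():
            tp[key[2]] += count
        for key, count in g.items():
            n_gold[key[2]] += count
        for key, count in p.items():
            n_pred[key[2]] += count
    types = set(n_gold) | set(n_pred)
    per_type = {t: _score(tp[t], n_pred[t], n_gold[t]) for t in types}
    return _aggregate(per_type, "strict")


def conll_entity_eval(
    gold: Sequence[TokenLabelSequence], pred: Sequence[TokenLabelSequence]
) -> EvalReport:
    """Chunk-level evaluation from IOB2 label sequences.

    Gold and predicted sequences must share tokenisation; chunks are
    extracted with lenient repair and matched exactly on (sequence,
    token range, type).
    """
    if len(gold) != len(pred):
        raise ValidationError(
            f"tokenisation mismatch: {len(gold)} gold vs {len(pred)} predicted sequences"
        )
    tp: Counter = Counter()
    n_gold: Counter = Counter()
    n_pred: Counter = Counter()
    for i, (g_seq, p_seq) in enumerate(zip(gold, pred)):
        if len(g_seq) != len(p_seq):
            raise ValidationError(f"sequence {i}: token count mismatch")
        g_chunks = Counter(iob2_chunks(g_seq.labels))
        p_chunks = Counter(iob2_chunks(p_seq.labels))
        for (_, _, name), count in (g_chunks & p_chunks).items():
            tp[name] += count
        for (_, _, name), count in g_chunks.items():
            n_gold[name] += count
        for (_, _, name), count in p_chunks.items():
            n_pred[name] += count
    types = set(n_gold) | set(n_pred)
    per_type = {t: _score(tp[t], n_pred[t], n_gold[t]) for t in types}
    return _aggregate(per_type, "conll")


def resolve_relations(doc: Document) -> list[ResolvedRelation]:
    """Resolve a document's relations to span-level triples for scoring."""
    spans = {a.entity_id: (a.start, a.end) for a in doc.annotations}
    return [(spans[r.head], spans[r.tail], r.rtype) for r in doc.relations]


RelationsByDoc = Union[
    Mapping[str, Sequence[ResolvedRelation]], Sequence[ResolvedRelation]
]


def _as_rel_mapping(relations: RelationsByDoc) -> Mapping[str, Sequence[ResolvedRelation]]:
    if isinstance(relations, Mapping):
        return relations
    return {"_": relations}


def relation_eval(gold: RelationsByDoc, pred: RelationsByDoc) -> EvalReport:
    """Relation scoring: head span, tail span and type must all match.

    Inputs are span-resolved triples (see :func:`resolve_relations`),
    flat or per-document; the ``none`` label participates as a type so
    negative-class performance is reported alongside the positives.
    """
    gold_map, pred_map = _as_rel_mapping(gold), _as_rel_mapping(pred)
    tp: Counter = Counter()
    n_gold: Counter = Counter()
    n_pred: Counter = Counter()
    for doc_id in set(gold_map) | set(pred_map):
        g = Counter(gold_map.get(doc_id, []))
        p = Counter(pred_map.get(doc_id, []))
        for (_, _, rtype), count in (g & p).items():
            tp[rtype] += count
        for (_, _, rtype), count in g.items():
            n_gold[rtype] += count
        for (_, _, rtype), count in p.items():
            n_pred[rtype] += count
    types = set(n_gold) | set(n_pred)
    per_type = {t: _score(tp[t], n_pred[t], n_gold[t]) for t in types}
    return _aggregate(per_type, "relations")
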