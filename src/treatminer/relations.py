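"""Relation-extraction data construction and a deterministic baseline.

Builds the candidate sets a relation classifier trains and predicts on —
sentence-window pairs labelled from gold, none-class balancing ("NCB"),
inline XML entity tags ("Tag") and merged long-range character contexts
("Long-range") — and supplies a proximity baseline predictor that links
each value to its nearest preceding in-sentence trait and each trait to
its nearest arthropod mention within the window bound.

The JSON-lines export (context text + head/tail offsets and types +
label) is the exchange format an external span-classification model
runner consumes and produces.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .corpus_io import (
    build_context_windows,
    build_long_range_context,
    sentence_index_of,
    split_sentences,
)
from .model import (
    ContextWindow,
    Document,
    EntityAnnotation,
    RELATION_SCHEMA,
    RelationAnnotation,
    ValidationError,
    assert_non_overlapping,
)

POSITIVE_LABELS = ("hasTrait", "hasValue", "hasQualifier")


@dataclass
class CandidatePair:
    """One head/tail entity pair with its context — the RE unit."""

    window: ContextWindow
    head_type: str
    tail_type: str
    label: str
    config_tags: set[str] = field(default_factory=set)

    def to_json_record(self) -> dict:
        w = self.window
        return {
            "doc_id": w.doc_id,
            "text": w.text,
            "head": {"start": w.head_offset[0], "end": w.head_offset[1],
                     "type": self.head_type},
            "tail": {"start": w.tail_offset[0], "end": w.tail_offset[1],
                     "type": self.tail_type},
            "label": self.label,
        }


def generate_candidates(
    doc: Document, max_sentences: int = 6
) -> list[CandidatePair]:
    """All typed entity pairs co-occurring within the sentence bound.

    Pair typing follows the relation schema (arthropod→trait,
    trait→value, arthropod→qualifier); the label is the gold relation
    type when the document links the pair, else ``none`` — so the
    candidate set includes the negative class a classifier needs.
    """
    assert_non_overlapping(doc.annotations)
    return [
        CandidatePair(
            window=w, head_type=w.head_type, tail_type=w.tail_type, label=w.label
        )
        for w in build_context_windows(doc, max_sentences=max_sentences)
    ]


def balance_none_class(
    candidates: Sequence[CandidatePair], seed: int
) -> list[CandidatePair]:
    """None-Class Balancing: down-sample ``none`` to the majority positive.

    The ``none``-labelled candidates are sampled uniformly at random
    (seeded) down to the count of the most frequent positive label;
    positives are untouched and original order is preserved.  With no
    positive labels at all, no ``none`` candidates are kept.
    """
    positive_idx = [i for i, c in enumerate(candidates) if c.label in POSITIVE_LABELS]
    none_idx = [i for i, c in enumerate(candidates) if c.label == "none"]
    counts: dict[str, int] = {}
    for i in positive_idx:
        label = candidates[i].label
        counts[label] = counts.get(label, 0) + 1
    target = max(counts.values()) if counts else 0
    if len(none_idx) > target:
        rng = random.Random(seed)
        none_idx = sorted(rng.sample(none_idx, target))
    out = []
    for i in sorted(set(positive_idx) | set(none_idx)):
        candidates[i].config_tags.add("NCB")
        out.append(candidates[i])
    return out


_TAG_RE = re.compile(r"</?(?:head|tail)(?:\s[^>]*)?>")


def inject_inline_tags(window: ContextWindow) -> str:
    """Wrap the head and tail spans in inline XML entity tags.

    ``<head type="…">…</head>`` / ``<tail type="…">…</tail>`` in document
    order; all other text is unchanged, so stripping the tags recovers
    the window text exactly.  Overlapping head/tail spans are invalid.
    """
    (hs, he), (ts, te) = window.head_offset, window.tail_offset
    if hs < te and ts < he:
        raise ValidationError(
            f"head {window.head_offset} and tail {window.tail_offset} overlap"
        )
    pieces = sorted(
        [(hs, he, "head", window.head_type), (ts, te, "tail", window.tail_type)]
    )
    text = window.text
    (s1, e1, role1, t1), (s2, e2, role2, t2) = pieces
    return (
        text[:s1]
        + f'<{role1} type="{t1}">' + text[s1:e1] + f"</{role1}>"
        + text[e1:s2]
        + f'<{role2} type="{t2}">' + text[s2:e2] + f"</{role2}>"
        + text[e2:]
    )


def strip_inline_tags(tagged: str) -> str:
    """Inverse of :func:`inject_inline_tags`."""
    return _TAG_RE.sub("", tagged)


def build_long_range_candidates(
    doc: Document, flank: int = 500, separator: str = "\n"
) -> list[CandidatePair]:
    """Long-range configuration: merged character-flank contexts for all
    typed pairs, labelled from gold (no sentence-distance bound)."""
    gold = {(r.head, r.tail): r.rtype for r in doc.relations if r.rtype != "none"}
    out = []
    for head in doc.annotations:
        for tail in doc.annotations:
            if head is tail:
                continue
            if RELATION_SCHEMA.get((head.etype, tail.etype)) is None:
                continue
            window = build_long_range_context(doc, head, tail, flank, separator)
            window.label = gold.get((head.entity_id, tail.entity_id), "none")
            out.append(
                CandidatePair(
                    window=window,
                    head_type=head.etype,
                    tail_type=tail.etype,
                    label=window.label,
                    config_tags={"Long-range"},
                )
            )
    return out


def write_jsonl(candidates: Sequence[CandidatePair], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for cand in candidates:
            fh.write(json.dumps(cand.to_json_record(), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Proximity baseline
# ---------------------------------------------------------------------------

def predict_proximity_relations(
    doc: Document,
    entities: Optional[Sequence[EntityAnnotation]] = None,
    max_sentences: int = 6,
) -> list[RelationAnnotation]:
    """Deterministic proximity baseline.

    Each value links to the nearest preceding trait in the same sentence
    (hasValue); each trait links to the nearest arthropod within the
    sentence-window bound, preferring preceding mentions (hasTrait).  One
    head per tail; only type-consistent relations are emitted.
    """
    if entities is None:
        entities = doc.annotations
    assert_non_overlapping(entities)
    sentences = split_sentences(doc)
    if not sentences:
        return []
    sent_of = {e.entity_id: sentence_index_of(sentences, e.start) for e in entities}
    arthropods = [e for e in entities if e.etype == "arthropod"]
    traits = [e for e in entities if e.etype == "trait"]
    values = [e for e in entities if e.etype == "value"]

    relations: list[RelationAnnotation] = []
    for value in values:
        in_sentence = [
            t for t in traits
            if sent_of[t.entity_id] == sent_of[value.entity_id] and t.end <= value.start
        ]
        if in_sentence:
            head = max(in_sentence, key=lambda t: t.end)  # nearest preceding
            relations.append(RelationAnnotation(head.entity_id, value.entity_id, "hasValue"))
    for trait in traits:
        in_range = [
            a for a in arthropods
            if abs(sent_of[a.entity_id] - sent_of[trait.entity_id]) + 1 <= max_sentences
        ]
        preceding = [a for a in in_range if a.end <= trait.start]
        if preceding:
            head = max(preceding, key=lambda a: a.end)
        elif in_range:
            head = min(in_range, key=lambda a: a.start)
        else:
            continue
        relations.append(RelationAnnotation(head.entity_id, trait.entity_id, "hasTrait"))
    return relations
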