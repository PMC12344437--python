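"""Core annotation data model.

Documents are plain text with character-offset annotation layers.  All
offsets are 0-based, half-open ``[start, end)`` over Unicode code points.
Four entity types form the annotation schema — ``arthropod`` (a taxon
mention), ``trait`` (a morphology / habitat / feeding-ecology property),
``value`` (a measurement, colour or other trait value) and ``qualifier``
(a life-stage or sex modifier such as "female" or "larva") — linked by
three directed relation types whose direction is fixed by the entity
types involved: arthropod→trait (``hasTrait``), trait→value
(``hasValue``) and arthropod→qualifier (``hasQualifier``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

ENTITY_TYPES = ("arthropod", "trait", "value", "qualifier")
RELATION_TYPES = ("hasTrait", "hasValue", "hasQualifier", "none")

#: entity-type pair -> the relation type that may link them (head -> tail)
RELATION_SCHEMA = {
    ("arthropod", "trait"): "hasTrait",
    ("trait", "value"): "hasValue",
    ("arthropod", "qualifier"): "hasQualifier",
}

#: IOB2 label names per entity type
IOB2_TYPE_NAMES = {
    "arthropod": "Arthropod",
    "trait": "Trait",
    "value": "Value",
    "qualifier": "Qualifier",
}
IOB2_TYPE_CODES = {v: k for k, v in IOB2_TYPE_NAMES.items()}

SPLIT_TAGS = ("TRAIN-GOLD", "TEST-GOLD")


class ValidationError(ValueError):
    """An annotation or document violates a structural invariant."""


@dataclass(frozen=True)
class EntityAnnotation:
    """A typed, contiguous character span in a document."""

    entity_id: str
    start: int
    end: int
    etype: str
    surface: str = ""
    concept_id: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValidationError(
                f"unknown entity type {self.etype!r}; expected one of {ENTITY_TYPES}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid span ({self.start}, {self.end}) for entity {self.entity_id!r}"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EntityAnnotation") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class RelationAnnotation:
    """A directed, typed link between two entities of one document."""

    head: str
    tail: str
    rtype: str

    def __post_init__(self) -> None:
        if self.rtype not in RELATION_TYPES:
            raise ValidationError(
                f"unknown relation type {self.rtype!r}; expected one of {RELATION_TYPES}"
            )


@dataclass
class Document:
    """Identified text carrying entity and relation annotation layers."""

    doc_id: str
    text: str
    annotations: list[EntityAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)
    split_tag: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.text)

    def validate(self) -> "Document":
        """Check all structural invariants; return self for chaining."""
        if self.split_tag is not None and self.split_tag not in SPLIT_TAGS:
            raise ValidationError(
                f"{self.doc_id}: unknown split tag {self.split_tag!r}"
            )
        by_id: dict[str, EntityAnnotation] = {}
        for ann in self.annotations:
            if ann.end > self.length:
                raise ValidationError(
                    f"{self.doc_id}: span ({ann.start}, {ann.end}) exceeds "
                    f"document length {self.length}"
                )
            if ann.surface and self.text[ann.start : ann.end] != ann.surface:
                raise ValidationError(
                    f"{self.doc_id}: surface {ann.surface!r} does not equal "
                    f"text[{ann.start}:{ann.end}] = "
                    f"{self.text[ann.start:ann.end]!r}"
                )
            if ann.entity_id in by_id:
                raise ValidationError(
                    f"{self.doc_id}: duplicate entity id {ann.entity_id!r}"
                )
            by_id[ann.entity_id] = ann
        for rel in self.relations:
            if rel.head not in by_id or rel.tail not in by_id:
                raise ValidationError(
                    f"{self.doc_id}: relation {rel.head}->{rel.tail} references "
                    "an unknown entity"
                )
            if rel.rtype != "none":
                pair = (by_id[rel.head].etype, by_id[rel.tail].etype)
                if RELATION_SCHEMA.get(pair) != rel.rtype:
                    raise ValidationError(
                        f"{self.doc_id}: relation type {rel.rtype!r} inconsistent "
                        f"with entity types {pair}"
                    )
        return self

    def entity(self, entity_id: str) -> EntityAnnotation:
        for ann in self.annotations:
            if ann.entity_id == entity_id:
                return ann
        raise KeyError(entity_id)

    def entities_of_type(self, etype: str) -> list[EntityAnnotation]:
        return [a for a in self.annotations if a.etype == etype]

    def with_surfaces(self) -> "Document":
        """Fill in each annotation's surface from the text slice."""
        filled = [
            replace(a, surface=self.text[a.start : a.end]) for a in self.annotations
        ]
        return Document(
            self.doc_id, self.text, filled, list(self.relations), self.split_tag
        )


@dataclass
class TokenLabelSequence:
    """One sentence as parallel token and IOB2 label sequences.

    ``tokens`` holds ``(surface, (start, end))`` pairs with document-level
    offsets; ``labels`` holds IOB2 tags such as ``B-Trait`` / ``I-Trait`` /
    ``O``.
    """

    tokens: list[tuple[str, tuple[int, int]]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValidationError(
                f"{len(self.tokens)} tokens but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class ContextWindow:
    """A sentence window around a candidate head/tail entity pair.

    ``head_offset`` and ``tail_offset`` are the entity spans rebased to
    ``text`` so that ``text[start:end]`` slices to the entity surface.
    """

    doc_id: str
    sentence_range: tuple[int, int]  # inclusive sentence indices
    text: str
    head_offset: tuple[int, int]
    tail_offset: tuple[int, int]
    head_type: str
    tail_type: str
    label: str = "none"

    def head_surface(self) -> str:
        return self.text[self.head_offset[0] : self.head_offset[1]]

    def tail_surface(self) -> str:
        return self.text[self.tail_offset[0] : self.tail_offset[1]]


def assert_non_overlapping(entities: Sequence[EntityAnnotation]) -> None:
    """Raise :class:`ValidationError` if any two entity spans overlap."""
    ordered = sorted(entities, key=lambda a: (a.start, a.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValidationError(
                f"overlapping entities {prev.entity_id!r} {prev.span} and "
                f"{cur.entity_id!r} {cur.span}; run merge_annotations first"
            )


def fresh_entity_ids(entities: Iterable[EntityAnnotation], prefix: str = "e") -> list[
    EntityAnnotation
]:
    """Re-number entities deterministically by document order."""
    ordered = sorted(entities, key=lambda a: (a.start, a.end, a.etype))
    return [replace(a, entity_id=f"{prefix}{i}") for i, a in enumerate(ordered)]
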