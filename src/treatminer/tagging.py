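"""Entity recognition.

Three deterministic recognisers — a gazetteer tagger driven by the taxon
and trait dictionaries (greedy longest match with tiered normalisation),
a pattern grammar for value entities (measurements, numeric lists,
percentages, colour descriptors) and a closed-lexicon qualifier tagger —
plus overlap resolution across layers and a plugin contract behind which
model-based taggers (transformer NER and the like) can be dropped in.

Gazetteer and pattern annotations carry score 1.0; plugin taggers supply
their own model confidences.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Protocol, Sequence, runtime_checkable

from .corpus_io import tokenize
from .dictionaries import Dictionary
from .model import Document, EntityAnnotation

#: overlap-resolution precedence (lower rank wins on equal span length)
TYPE_PRECEDENCE = {"arthropod": 0, "trait": 1, "value": 2, "qualifier": 3}

QUALIFIER_LEXICON = frozenset(
    {"female", "male", "juvenile", "larva", "adult", "nymph", "pupa",
     "females", "males", "juveniles", "larvae", "adults", "nymphs", "pupae"}
)

UNIT_LEXICON = ("mm", "cm", "µm", "μm", "km", "mg", "kg", "m", "g", "%")

COLOR_LEXICON = (
    "yellow", "yellowish", "brown", "brownish", "black", "blackish",
    "white", "whitish", "red", "reddish", "grey", "gray", "greyish",
    "green", "greenish", "blue", "bluish", "orange", "ochre", "fuscous",
    "testaceous", "ferruginous", "pale", "dark",
)

_NUM = r"\d+(?:\.\d+)?"
_UNIT = "|".join(re.escape(u) for u in sorted(UNIT_LEXICON, key=len, reverse=True))
_COLOR = "|".join(sorted(COLOR_LEXICON, key=len, reverse=True))

#: value pattern grammar, tried in order; longer/earlier matches win at merge
VALUE_PATTERNS = (
    # comma-separated numeric series: "38, 47, 43, 41, 33, 21"
    ("range_list", re.compile(rf"{_NUM}(?:\s*,\s*{_NUM})+")),
    # measurement with unit, optionally a range: "56.6 mm", "3–5 mm", "12 %"
    ("measurement", re.compile(rf"{_NUM}(?:\s*[–—-]\s*{_NUM})?\s*(?:{_UNIT})(?![A-Za-z])")),
    # bare decimal in measurement context (a length/size keyword just before)
    ("number", re.compile(
        rf"(?:length|width|height|depth|size|diameter)\s+(?:of\s+)?({_NUM})",
        re.IGNORECASE,
    )),
    # colour descriptors incl. hyphenated compounds: "brownish-yellow"
    ("color", re.compile(rf"\b(?:{_COLOR})(?:-(?:{_COLOR}))*\b", re.IGNORECASE)),
)


@runtime_checkable
class TaggerPlugin(Protocol):
    """Contract for external (model-based) taggers.

    A plugin has a ``name`` and a ``tag`` method mapping a document to
    entity annotations whose spans are valid for the document and whose
    scores lie in [0, 1].  Plugins interoperate via BioC JSON, so an
    external model runner only needs to read and write that format.
    """

    name: str

    def tag(self, doc: Document) -> list[EntityAnnotation]:
        ...


_PLUGIN_REGISTRY: dict[str, TaggerPlugin] = {}


def register_plugin(plugin: TaggerPlugin) -> None:
    _PLUGIN_REGISTRY[plugin.name] = plugin


def get_plugin(name: str) -> TaggerPlugin:
    try:
        return _PLUGIN_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no tagger plugin registered under {name!r}; "
            f"known: {sorted(_PLUGIN_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Gazetteer tagging
# ---------------------------------------------------------------------------

def tag_with_dictionary(
    doc: Document, dictionary: Dictionary, etype: Optional[str] = None
) -> list[EntityAnnotation]:
    """Greedy longest-match gazetteer tagging.

    Token n-grams (longest first) are looked up through the dictionary's
    tiered index (exact → case-folded → plural-stripped); a hit emits an
    entity of the dictionary's kind with its concept id and score 1.0 and
    tagging resumes after the matched tokens.  Ambiguous hits resolve to
    the lexicographically smallest concept id.
    """
    if len(dictionary) == 0:
        return []
    if etype is None:
        kinds = {c.kind for c in dictionary}
        etype = "arthropod" if kinds == {"taxon"} else "trait"
    tokens = tokenize(doc.text)
    max_n = dictionary.max_term_tokens()
    entities: list[EntityAnnotation] = []
    i, n_emitted = 0, 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            start = tokens[i][1][0]
            end = tokens[i + n - 1][1][1]
            surface = doc.text[start:end]
            hits, _tier = dictionary.lookup(surface)
            if hits:
                entities.append(
                    EntityAnnotation(
                        entity_id=f"{etype}-gz{n_emitted}",
                        start=start,
                        end=end,
                        etype=etype,
                        surface=surface,
                        concept_id=min(hits),
                        score=1.0,
                    )
                )
                n_emitted += 1
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return entities


# ---------------------------------------------------------------------------
# Value and qualifier tagging
# ---------------------------------------------------------------------------

def tag_values(doc: Document) -> list[EntityAnnotation]:
    """Pattern-based value recognition.

    Emits maximal spans for numeric series, number+unit measurements,
    keyword-anchored bare numbers and colour descriptors; overlapping
    matches are resolved longest-first so "5.6" inside "5.6 mm" never
    surfaces as a separate entity.  Bare location values (e.g. country
    names) are out of the pattern grammar's reach and are not tagged.
    """
    raw: list[tuple[int, int]] = []
    for kind, pattern in VALUE_PATTERNS:
        for m in pattern.finditer(doc.text):
            if kind == "number":
                raw.append(m.span(1))
            else:
                raw.append(m.span())
    kept: list[tuple[int, int]] = []
    for span in sorted(raw, key=lambda s: (-(s[1] - s[0]), s[0])):
        if all(span[1] <= k[0] or k[1] <= span[0] for k in kept):
            kept.append(span)
    kept.sort()
    return [
        EntityAnnotation(
            entity_id=f"value-p{i}",
            start=s,
            end=e,
            etype="value",
            surface=doc.text[s:e],
            score=1.0,
        )
        for i, (s, e) in enumerate(kept)
    ]


def tag_qualifiers(doc: Document) -> list[EntityAnnotation]:
    """Closed-lexicon tagging of life-stage/sex qualifiers."""
    entities = []
    for i, (surface, (s, e)) in enumerate(tokenize(doc.text)):
        if surface.casefold() in QUALIFIER_LEXICON:
            entities.append(
                EntityAnnotation(
                    entity_id=f"qualifier-l{i}",
                    start=s,
                    end=e,
                    etype="qualifier",
                    surface=surface,
                    score=1.0,
                )
            )
    return entities


# ---------------------------------------------------------------------------
# Overlap resolution
# ---------------------------------------------------------------------------

def merge_annotations(
    *layers: Sequence[EntityAnnotation],
) -> list[EntityAnnotation]:
    """Resolve overlaps across annotation layers.

    Longer span wins; equal length resolves by entity-type precedence
    (arthropod > trait > value > qualifier), then by leftmost start.  The
    result is overlap-free, in document order, and independent of the
    input order of layers and annotations.
    """
    pool = [a for layer in layers for a in layer]
    pool.sort(
        key=lambda a: (-(a.end - a.start), TYPE_PRECEDENCE[a.etype], a.start, a.end,
                       a.concept_id or "", a.entity_id)
    )
    accepted: list[EntityAnnotation] = []
    for cand in pool:
        if all(not cand.overlaps(a) for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda a: (a.start, a.end))
    return accepted


def tag_document(
    doc: Document,
    taxa: Optional[Dictionary] = None,
    traits: Optional[Dictionary] = None,
    values: bool = True,
    qualifiers: bool = True,
    plugins: Iterable[TaggerPlugin] = (),
) -> Document:
    """Run the selected recognisers and return a document with the merged,
    overlap-free entity layer (entities renumbered in document order)."""
    layers: list[list[EntityAnnotation]] = []
    if taxa is not None:
        layers.append(tag_with_dictionary(doc, taxa, etype="arthropod"))
    if traits is not None:
        layers.append(tag_with_dictionary(doc, traits, etype="trait"))
    if values:
        layers.append(tag_values(doc))
    if qualifiers:
        layers.append(tag_qualifiers(doc))
    for plugin in plugins:
        layers.append(plugin.tag(doc))
    merged = merge_annotations(*layers)
    renumbered = [
        EntityAnnotation(
            entity_id=f"e{i}",
            start=a.start,
            end=a.end,
            etype=a.etype,
            surface=a.surface,
            concept_id=a.concept_id,
            score=a.score,
        )
        for i, a in enumerate(merged)
    ]
    return Document(doc.doc_id, doc.text, renumbered, [], doc.split_tag)
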