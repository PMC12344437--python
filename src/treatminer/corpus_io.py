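"""Document I/O and format conversion.

Reads and writes annotated documents as BioC JSON (the interchange format
the whole toolkit is built on), converts offset-annotated text to and
from IOB2 token sequences in CoNLL layout, and builds the sentence-window
and long-range character contexts that relation extraction consumes.

Conventions
-----------
* Offsets are 0-based half-open ``[start, end)`` over Unicode code points.
* A multi-passage BioC document is concatenated into one text with a
  single ``"\\n"`` separator between passages; annotation offsets stored
  passage-locally are rebased to the concatenated text on read.
* CoNLL files carry one ``token<TAB>label`` per line with a blank line
  between sentences.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import (
    ContextWindow,
    Document,
    EntityAnnotation,
    IOB2_TYPE_CODES,
    IOB2_TYPE_NAMES,
    RELATION_SCHEMA,
    RelationAnnotation,
    TokenLabelSequence,
    ValidationError,
    assert_non_overlapping,
)

PASSAGE_SEPARATOR = "\n"

#: tokens after which a sentence never ends (taxonomic and common abbreviations)
ABBREVIATION_GUARDS = frozenset(
    {"sp.", "spp.", "nov.", "cf.", "aff.", "e.g.", "i.e.", "fig.", "figs.",
     "et al.", "al.", "gen.", "var.", "subsp.", "ca.", "approx.", "no."}
)

_PUNCT_CHARS = ".,;:()[]\"'—"


class FormatError(ValueError):
    """Input file does not conform to the expected format."""


# ---------------------------------------------------------------------------
# BioC JSON
# ---------------------------------------------------------------------------

def _entity_to_bioc(ann: EntityAnnotation) -> dict:
    infons = {"type": ann.etype}
    if ann.concept_id is not None:
        infons["identifier"] = ann.concept_id
    if ann.score is not None:
        infons["score"] = repr(ann.score)
    return {
        "id": ann.entity_id,
        "infons": infons,
        "text": ann.surface,
        "locations": [{"offset": ann.start, "length": ann.end - ann.start}],
    }


def _relation_to_bioc(rel: RelationAnnotation) -> dict:
    return {
        "infons": {"type": rel.rtype},
        "nodes": [
            {"refid": rel.head, "role": "head"},
            {"refid": rel.tail, "role": "tail"},
        ],
    }


def write_bioc_collection(docs: Sequence[Document], path: Union[str, Path]) -> None:
    """Serialise documents as a BioC JSON collection file.

    Each document is written as a single passage holding the full text, so
    annotation offsets in the file equal the in-memory global offsets and
    :func:`read_bioc_collection` round-trips exactly.
    """
    collection = {
        "source": "treatminer",
        "date": "",
        "key": "treatminer.key",
        "infons": {},
        "documents": [],
    }
    for doc in docs:
        doc.validate()
        infons = {}
        if doc.split_tag is not None:
            infons["split"] = doc.split_tag
        collection["documents"].append(
            {
                "id": doc.doc_id,
                "infons": infons,
                "passages": [
                    {
                        "offset": 0,
                        "infons": {},
                        "text": doc.text,
                        "annotations": [
                            _entity_to_bioc(a) for a in doc.with_surfaces().annotations
                        ],
                        "relations": [],
                    }
                ],
                "relations": [_relation_to_bioc(r) for r in doc.relations],
            }
        )
    Path(path).write_text(
        json.dumps(collection, ensure_ascii=False, indent=1), encoding="utf-8"
    )


def _parse_bioc_annotation(raw: dict, passage_start: int, doc_id: str) -> EntityAnnotation:
    try:
        loc = raw["locations"][0]
        start = passage_start + int(loc["offset"])
        end = start + int(loc["length"])
        infons = raw.get("infons", {})
        etype = infons["type"]
    except (KeyError, IndexError, TypeError) as exc:
        raise FormatError(f"{doc_id}: malformed BioC annotation {raw!r}") from exc
    score = infons.get("score")
    return EntityAnnotation(
        entity_id=str(raw.get("id", "")),
        start=start,
        end=end,
        etype=etype,
        surface=raw.get("text", ""),
        concept_id=infons.get("identifier"),
        score=float(score) if score is not None else None,
    )


def _parse_bioc_relation(raw: dict, doc_id: str) -> RelationAnnotation:
    nodes = {n.get("role"): n.get("refid") for n in raw.get("nodes", [])}
    if "head" not in nodes or "tail" not in nodes:
        # fall back to node order when roles are absent
        ordered = [n.get("refid") for n in raw.get("nodes", [])]
        if len(ordered) != 2:
            raise FormatError(f"{doc_id}: relation does not connect exactly two entities")
        nodes = {"head": ordered[0], "tail": ordered[1]}
    rtype = raw.get("infons", {}).get("type", "none")
    return RelationAnnotation(head=nodes["head"], tail=nodes["tail"], rtype=rtype)


def read_bioc_collection(path: Union[str, Path]) -> list[Document]:
    """Read a BioC JSON collection into documents.

    Passages are concatenated with a single newline separator; annotation
    offsets (stored relative to their passage) are rebased to the
    concatenated text.  Out-of-range offsets raise :class:`ValidationError`
    naming the document and span.
    """
    try:
        collection = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid BioC JSON ({exc})") from exc
    if "documents" not in collection:
        raise FormatError(f"{path}: missing 'documents' key")

    docs: list[Document] = []
    for raw_doc in collection["documents"]:
        doc_id = str(raw_doc.get("id", ""))
        parts: list[str] = []
        annotations: list[EntityAnnotation] = []
        relations: list[RelationAnnotation] = []
        offset = 0
        for passage in raw_doc.get("passages", []):
            text = passage.get("text", "")
            for raw_ann in passage.get("annotations", []):
                annotations.append(_parse_bioc_annotation(raw_ann, offset, doc_id))
            for raw_rel in passage.get("relations", []):
                relations.append(_parse_bioc_relation(raw_rel, doc_id))
            parts.append(text)
            offset += len(text) + len(PASSAGE_SEPARATOR)
        for raw_rel in raw_doc.get("relations", []):
            relations.append(_parse_bioc_relation(raw_rel, doc_id))
        full_text = PASSAGE_SEPARATOR.join(parts)
        for ann in annotations:
            if ann.end > len(full_text):
                raise ValidationError(
                    f"{doc_id}: annotation span ({ann.start}, {ann.end}) outside "
                    f"document of length {len(full_text)}"
                )
        split = raw_doc.get("infons", {}).get("split")
        doc = Document(doc_id, full_text, annotations, relations, split)
        docs.append(doc.with_surfaces().validate())
    return docs


# ---------------------------------------------------------------------------
# Tokenisation and sentence splitting
# ---------------------------------------------------------------------------

def tokenize(text: str, base: int = 0) -> list[tuple[str, tuple[int, int]]]:
    """Split text into ``(surface, (start, end))`` tokens.

    Whitespace-delimited chunks are further split by peeling leading and
    trailing punctuation into separate tokens.  Hyphenated compounds
    ("brownish-yellow") and decimal numbers ("56.6") stay whole: an
    internal ``.`` or ``-`` never splits a token.
    """
    tokens: list[tuple[str, tuple[int, int]]] = []
    for m in re.finditer(r"\S+", text):
        chunk, start = m.group(), base + m.start()
        # peel leading punctuation
        while chunk and chunk[0] in _PUNCT_CHARS:
            tokens.append((chunk[0], (start, start + 1)))
            chunk, start = chunk[1:], start + 1
        # peel trailing punctuation
        trailing: list[tuple[str, tuple[int, int]]] = []
        while chunk and chunk[-1] in _PUNCT_CHARS:
            end = start + len(chunk)
            trailing.append((chunk[-1], (end - 1, end)))
            chunk = chunk[:-1]
        if chunk:
            tokens.append((chunk, (start, start + len(chunk))))
        tokens.extend(reversed(trailing))
    return tokens


def _is_guarded(text: str, period_idx: int) -> bool:
    """True when the period at ``period_idx`` ends a guarded abbreviation."""
    start = period_idx
    while start > 0 and not text[start - 1].isspace():
        start -= 1
    word = text[start : period_idx + 1]
    if word.lower() in ABBREVIATION_GUARDS:
        return True
    # single-capital genus abbreviation, e.g. "T."
    if len(word) == 2 and word[0].isupper() and word[1] == ".":
        return True
    return False


def split_sentences(doc_or_text: Union[Document, str]) -> list[tuple[int, int]]:
    """Rule-based sentence spans over a document's text.

    A sentence ends at ``. ! ?`` followed by whitespace and a capital
    letter, digit, quote or opening bracket — unless the terminator closes
    a guarded abbreviation (genus initials "T.", "sp.", "nov.", "e.g.", …).
    Returned spans are ordered, non-overlapping and trimmed to
    non-whitespace; together they cover all non-whitespace text.
    """
    text = doc_or_text.text if isinstance(doc_or_text, Document) else doc_or_text
    if not text.strip():
        return []
    boundaries: list[int] = []
    for m in re.finditer(r"[.!?]+(?=\s+[\"'(\[]?[A-Z0-9])", text):
        last = m.end() - 1
        if text[last] == "." and _is_guarded(text, last):
            continue
        boundaries.append(m.end())
    # also break on paragraph separators
    for m in re.finditer(r"\n", text):
        boundaries.append(m.start())
    boundaries = sorted(set(boundaries))

    spans: list[tuple[int, int]] = []
    prev = 0
    for b in boundaries + [len(text)]:
        seg = text[prev:b]
        stripped = seg.strip()
        if stripped:
            lead = len(seg) - len(seg.lstrip())
            spans.append((prev + lead, prev + lead + len(stripped)))
        prev = b
    return spans


def sentence_index_of(sentences: Sequence[tuple[int, int]], offset: int) -> int:
    """Index of the sentence containing ``offset`` (nearest if in a gap)."""
    for i, (s, e) in enumerate(sentences):
        if s <= offset < e:
            return i
    for i, (s, e) in enumerate(sentences):
        if offset < s:
            return max(i - 1, 0) if offset >= (sentences[i - 1][1] if i else 0) else i
    if sentences:
        return len(sentences) - 1
    raise ValidationError(f"offset {offset} lies outside every sentence")


# ---------------------------------------------------------------------------
# IOB2 / CoNLL
# ---------------------------------------------------------------------------

def entities_to_iob2(doc: Document) -> list[TokenLabelSequence]:
    """Project a document's entity layer onto IOB2-labelled token sentences.

    Any token whose span intersects an entity is labelled with that
    entity's type — the first intersecting token ``B-``, the rest ``I-``
    (an entity boundary inside a token expands to the whole token).
    Entities must be non-overlapping; merge layers first.
    """
    assert_non_overlapping(doc.annotations)
    entities = sorted(doc.annotations, key=lambda a: a.start)
    sequences: list[TokenLabelSequence] = []
    for s_start, s_end in split_sentences(doc):
        tokens = tokenize(doc.text[s_start:s_end], base=s_start)
        labels: list[str] = []
        prev_entity: Optional[EntityAnnotation] = None
        for _, (t_start, t_end) in tokens:
            hit = next(
                (e for e in entities if e.start < t_end and t_start < e.end), None
            )
            if hit is None:
                labels.append("O")
            elif hit is prev_entity:
                labels.append(f"I-{IOB2_TYPE_NAMES[hit.etype]}")
            else:
                labels.append(f"B-{IOB2_TYPE_NAMES[hit.etype]}")
            prev_entity = hit
        sequences.append(TokenLabelSequence(tokens, labels))
    return sequences


def iob2_chunks(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    """Extract ``(first_token, last_token, type)`` chunks with lenient repair.

    conlleval-compatible: an orphan ``I-X`` (after ``O``, at the start, or
    after a different type) opens a new chunk; a ``B-`` always opens one.
    """
    chunks: list[tuple[int, int, str]] = []
    cur_start: Optional[int] = None
    cur_type: Optional[str] = None
    for i, label in enumerate(labels):
        if label == "O" or label is None:
            if cur_start is not None:
                chunks.append((cur_start, i - 1, cur_type))
                cur_start = cur_type = None
            continue
        prefix, _, name = label.partition("-")
        if prefix == "B" or cur_type != name:
            if cur_start is not None:
                chunks.append((cur_start, i - 1, cur_type))
            cur_start, cur_type = i, name
    if cur_start is not None:
        chunks.append((cur_start, len(labels) - 1, cur_type))
    return chunks


def iob2_to_entities(
    sequences: Iterable[TokenLabelSequence], id_prefix: str = "e"
) -> list[EntityAnnotation]:
    """Recover entity annotations from IOB2 token sequences.

    Inverse of :func:`entities_to_iob2` for non-overlapping,
    token-aligned entities; ill-formed label runs are repaired per
    :func:`iob2_chunks`.
    """
    entities: list[EntityAnnotation] = []
    n = 0
    for seq in sequences:
        for first, last, name in iob2_chunks(seq.labels):
            start = seq.tokens[first][1][0]
            end = seq.tokens[last][1][1]
            entities.append(
                EntityAnnotation(
                    entity_id=f"{id_prefix}{n}",
                    start=start,
                    end=end,
                    etype=IOB2_TYPE_CODES[name],
                )
            )
            n += 1
    return entities


def write_conll(sequences: Iterable[TokenLabelSequence], path: Union[str, Path]) -> None:
    """Write token/label sequences as a CoNLL file (token TAB label)."""
    lines: list[str] = []
    for seq in sequences:
        for (surface, _), label in zip(seq.tokens, seq.labels):
            lines.append(f"{surface}\t{label}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_conll(path: Union[str, Path]) -> list[TokenLabelSequence]:
    """Read a CoNLL file; token offsets are synthesised left to right."""
    sequences: list[TokenLabelSequence] = []
    tokens: list[tuple[str, tuple[int, int]]] = []
    labels: list[str] = []
    pos = 0
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            if tokens:
                sequences.append(TokenLabelSequence(tokens, labels))
                tokens, labels = [], []
            continue
        surface, _, label = line.partition("\t")
        tokens.append((surface, (pos, pos + len(surface))))
        labels.append(label or "O")
        pos += len(surface) + 1
    if tokens:
        sequences.append(TokenLabelSequence(tokens, labels))
    return sequences


# ---------------------------------------------------------------------------
# Context windows
# ---------------------------------------------------------------------------

def _typed_pairs(
    entities: Sequence[EntityAnnotation],
) -> list[tuple[EntityAnnotation, EntityAnnotation, str]]:
    pairs = []
    for head in entities:
        for tail in entities:
            if head is tail:
                continue
            rtype = RELATION_SCHEMA.get((head.etype, tail.etype))
            if rtype is not None:
                pairs.append((head, tail, rtype))
    return pairs


def build_context_windows(
    doc: Document, max_sentences: int = 6
) -> list[ContextWindow]:
    """Sentence-window candidates for every typed entity pair in range.

    One window per (arthropod, trait), (trait, value) or (arthropod,
    qualifier) pair whose entities co-occur within ``max_sentences``
    consecutive sentences; the window is the minimal sentence range
    covering both.  The label is the gold relation type when the document
    links the pair, otherwise ``"none"``.
    """
    sentences = split_sentences(doc)
    gold = {(r.head, r.tail): r.rtype for r in doc.relations if r.rtype != "none"}
    windows: list[ContextWindow] = []
    for head, tail, _ in _typed_pairs(doc.annotations):
        si = sentence_index_of(sentences, head.start)
        sj = sentence_index_of(sentences, tail.start)
        lo, hi = min(si, sj), max(si, sj)
        if hi - lo + 1 > max_sentences:
            continue
        w_start, w_end = sentences[lo][0], sentences[hi][1]
        windows.append(
            ContextWindow(
                doc_id=doc.doc_id,
                sentence_range=(lo, hi),
                text=doc.text[w_start:w_end],
                head_offset=(head.start - w_start, head.end - w_start),
                tail_offset=(tail.start - w_start, tail.end - w_start),
                head_type=head.etype,
                tail_type=tail.etype,
                label=gold.get((head.entity_id, tail.entity_id), "none"),
            )
        )
    return windows


def build_long_range_context(
    doc: Document,
    head: EntityAnnotation,
    tail: EntityAnnotation,
    flank: int = 500,
    separator: str = "\n",
) -> ContextWindow:
    """Character-flank context for a (possibly distant) entity pair.

    Each entity is excised together with ``flank`` surrounding characters
    in total (half before, half after, clipped to document bounds); when
    the two slices overlap they are merged into one, otherwise they are
    joined with ``separator``.  Rebased offsets slice to the surfaces.
    """
    if head.span == tail.span:
        raise ValidationError("head and tail must be distinct entities")
    left = flank // 2
    right = flank - left

    def slice_of(e: EntityAnnotation) -> tuple[int, int]:
        return (max(0, e.start - left), min(doc.length, e.end + right))

    first, second = (head, tail) if head.start <= tail.start else (tail, head)
    (a0, a1), (b0, b1) = slice_of(first), slice_of(second)

    if b0 <= a1:  # overlapping or adjacent -> merge without duplication
        text = doc.text[a0 : max(a1, b1)]
        offsets = {
            first.entity_id: (first.start - a0, first.end - a0),
            second.entity_id: (second.start - a0, second.end - a0),
        }
    else:
        text = doc.text[a0:a1] + separator + doc.text[b0:b1]
        shift = (a1 - a0) + len(separator) - b0
        offsets = {
            first.entity_id: (first.start - a0, first.end - a0),
            second.entity_id: (second.start + shift, second.end + shift),
        }
    return ContextWindow(
        doc_id=doc.doc_id,
        sentence_range=(-1, -1),
        text=text,
        head_offset=offsets[head.entity_id],
        tail_offset=offsets[tail.entity_id],
        head_type=head.etype,
        tail_type=tail.etype,
    )


# ---------------------------------------------------------------------------
# Minimal JATS/XML text extraction and PubAnnotation export
# ---------------------------------------------------------------------------

def extract_xml_text(xml_source: str) -> str:
    """Strip tags from an XML fragment, keeping element text in order."""
    from lxml import etree

    root = etree.fromstring(xml_source.encode("utf-8"))
    return "".join(root.itertext())


def to_pubannotation(doc: Document) -> dict:
    """Export one document in PubAnnotation JSON form (viewer interop)."""
    doc = doc.with_surfaces()
    return {
        "text": doc.text,
        "sourceid": doc.doc_id,
        "denotations": [
            {
                "id": a.entity_id,
                "span": {"begin": a.start, "end": a.end},
                "obj": a.etype,
            }
            for a in doc.annotations
        ],
        "relations": [
            {
                "id": f"r{i}",
                "subj": r.head,
                "obj": r.tail,
                "pred": r.rtype,
            }
            for i, r in enumerate(doc.relations)
        ],
    }
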