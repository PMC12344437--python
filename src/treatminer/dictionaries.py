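"""Taxon and trait dictionaries for gazetteer tagging and normalisation.

The taxon dictionary is built from a Darwin-Core-style checklist (columns
``taxonID``, ``parentNameUsageID``, ``scientificName``,
``taxonomicStatus``, ``taxonRank``) by extracting every *accepted* taxon
hierarchically below a chosen root, each carrying its ascending lineage
of ancestor names.  The trait dictionary is loaded from a curated
spreadsheet/TSV (term, category, trait type, synonyms, source URI) with
the three trait categories feeding ecology, habitat and morphology.

Surface lookup is tiered: exact form, case-folded + whitespace-collapsed
form, plural-stripped form.  Single-word taxon surfaces (genus names and
other capitalised names) are indexed case-sensitively only, since taxon
capitalisation is informative and common words would otherwise collide.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .corpus_io import tokenize
from .model import Document

TRAIT_CATEGORIES = ("feeding ecology", "habitat", "morphology")
TRAIT_TYPES = ("yes/no", "association", "measurement", "length/width", "count")
TAXON_RANKS = ("species", "genus", "family", "order", "class", "phylum")

CHECKLIST_COLUMNS = (
    "taxonID",
    "parentNameUsageID",
    "scientificName",
    "taxonomicStatus",
    "taxonRank",
)


class DictionaryError(ValueError):
    """A dictionary input violates its schema or structure."""


def normalize_surface(surface: str) -> str:
    """Normalisation key: case-folded with internal whitespace collapsed."""
    return re.sub(r"\s+", " ", surface.strip()).casefold()


def strip_plural(word: str) -> Optional[str]:
    """Regular-English singular of ``word``, or None if no rule applies.

    Latinate ``-is`` / ``-us`` endings (proboscis, tarsus) and ``-ss``
    words are left alone: their inflection is irregular.
    """
    if word.endswith(("is", "us", "ss")):
        return None
    if word.endswith("ies") and len(word) > 3:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "xes", "zes", "ses")) and len(word) > 4:
        return word[:-2]
    if word.endswith("s") and len(word) > 2:
        return word[:-1]
    return None


def pluralize(word: str) -> Optional[str]:
    """Regular-English plural of ``word``, or None if no safe rule applies.

    Words already ending in ``s`` (including latinate forms such as
    "proboscis") are skipped: their plurals are irregular and belong in
    the curated synonyms column instead.
    """
    if not word or word.endswith("s"):
        return None
    if word.endswith("y") and len(word) > 1 and word[-2] not in "aeiou":
        return word[:-1] + "ies"
    if word.endswith(("ch", "sh", "x", "z")):
        return word + "es"
    return word + "s"


@dataclass
class Concept:
    """A normalisation target: one taxon or one curated trait."""

    concept_id: str
    preferred_term: str
    kind: str  # {taxon, trait}
    category: str  # taxon rank or trait category
    synonyms: list[str] = field(default_factory=list)
    trait_type: Optional[str] = None
    lineage: list[str] = field(default_factory=list)
    source_uri: Optional[str] = None

    def surface_forms(self) -> list[str]:
        """Preferred term plus synonyms, case-insensitively de-duplicated."""
        forms: list[str] = []
        seen: set[str] = set()
        for form in [self.preferred_term, *self.synonyms]:
            key = normalize_surface(form)
            if key and key not in seen:
                seen.add(key)
                forms.append(form)
        return forms


class Dictionary:
    """An id-indexed concept collection with a derived surface index."""

    def __init__(self, concepts: Iterable[Concept] = ()):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            self.add(c)

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise DictionaryError(f"duplicate concept id {concept.concept_id!r}")
        if not concept.preferred_term:
            raise DictionaryError(f"{concept.concept_id}: empty preferred term")
        self.concepts[concept.concept_id] = concept
        self._index = None

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        return self.concepts[concept_id]

    def __iter__(self):
        return iter(self.concepts.values())

    # -- surface index ----------------------------------------------------

    _index: Optional[tuple[dict, dict]] = None

    def _build_index(self) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
        """(exact raw surface -> ids, normalised surface -> ids)."""
        exact: dict[str, set[str]] = {}
        folded: dict[str, set[str]] = {}
        for cid in sorted(self.concepts):
            concept = self.concepts[cid]
            for form in concept.surface_forms():
                exact.setdefault(form, set()).add(cid)
                if self._case_sensitive_only(concept, form):
                    continue
                folded.setdefault(normalize_surface(form), set()).add(cid)
        return exact, folded

    @staticmethod
    def _case_sensitive_only(concept: Concept, form: str) -> bool:
        # single-word capitalised taxon names (genus etc.) match exactly only
        return (
            concept.kind == "taxon"
            and " " not in form.strip()
            and form[:1].isupper()
        )

    @property
    def surface_index(self) -> dict[str, set[str]]:
        if self._index is None:
            self._index = self._build_index()
        return self._index[1]

    @property
    def exact_index(self) -> dict[str, set[str]]:
        if self._index is None:
            self._index = self._build_index()
        return self._index[0]

    def max_term_tokens(self) -> int:
        longest = 1
        for surface in self.exact_index:
            longest = max(longest, len(surface.split()))
        return longest

    def lookup(self, surface: str) -> tuple[Optional[set[str]], Optional[str]]:
        """Tiered surface lookup.

        Tiers: exact raw form; case-folded/whitespace-collapsed form;
        plural-stripped form.  Returns ``(concept_ids, tier_name)`` for the
        first tier with a hit, else ``(None, None)``.
        """
        hit = self.exact_index.get(surface)
        if hit:
            return hit, "exact"
        key = normalize_surface(surface)
        hit = self.surface_index.get(key)
        if hit:
            return hit, "folded"
        words = key.split()
        if words:
            singular = strip_plural(words[-1])
            if singular is not None:
                hit = self.surface_index.get(" ".join(words[:-1] + [singular]))
                if hit:
                    return hit, "plural"
        return None, None

    def category_counts(self) -> dict[str, int]:
        counts: Counter = Counter(c.category for c in self)
        return dict(counts)

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.concepts):
            c = self.concepts[cid]
            rows.append(
                {
                    "concept_id": c.concept_id,
                    "preferred_term": c.preferred_term,
                    "kind": c.kind,
                    "category": c.category,
                    "trait_type": c.trait_type or "",
                    "synonyms": "; ".join(c.synonyms),
                    "lineage": " | ".join(c.lineage),
                    "source_uri": c.source_uri or "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "concept_id", "preferred_term", "kind", "category",
                "trait_type", "synonyms", "lineage", "source_uri",
            ],
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "Dictionary":
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        concepts = []
        for row in frame.itertuples(index=False):
            concepts.append(
                Concept(
                    concept_id=row.concept_id,
                    preferred_term=row.preferred_term,
                    kind=row.kind,
                    category=row.category,
                    trait_type=row.trait_type or None,
                    synonyms=[s for s in row.synonyms.split("; ") if s],
                    lineage=[s for s in row.lineage.split(" | ") if s],
                    source_uri=row.source_uri or None,
                )
            )
        return cls(concepts)


# ---------------------------------------------------------------------------
# Taxon dictionary from a Darwin-Core checklist
# ---------------------------------------------------------------------------

def _read_table(source: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    path = Path(source)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=str)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def build_taxon_dictionary(
    checklist: Union[str, Path, pd.DataFrame],
    root_id: str,
    accepted_status: str = "accepted",
) -> Dictionary:
    """Accepted taxa below ``root_id``, each with its ascending lineage.

    Only rows whose ``taxonomicStatus`` equals ``accepted_status`` are
    considered, both as concepts and as lineage links — a non-accepted
    parent breaks the path, so its descendants are unreachable.  The root
    itself contributes its name to lineages but is not a concept.
    """
    table = _read_table(checklist).fillna("")
    missing = [c for c in CHECKLIST_COLUMNS if c not in table.columns]
    if missing:
        raise DictionaryError(f"checklist missing column(s): {', '.join(missing)}")

    names: dict[str, str] = {}
    ranks: dict[str, str] = {}
    parents: dict[str, str] = {}
    children: dict[str, list[str]] = {}
    for row in table.itertuples(index=False):
        tid = str(row.taxonID)
        names[tid] = str(row.scientificName)
        ranks[tid] = str(row.taxonRank)
        if tid == root_id:
            continue
        if str(row.taxonomicStatus) != accepted_status:
            continue
        parent = str(row.parentNameUsageID)
        parents[tid] = parent
        children.setdefault(parent, []).append(tid)

    # depth-first reachability from the root over accepted links
    reachable: list[str] = []
    seen: set[str] = set()
    stack = sorted(children.get(root_id, []), reverse=True)
    path_guard: set[str] = set()
    while stack:
        tid = stack.pop()
        if tid in seen:
            raise DictionaryError(f"parent cycle involving taxon {tid!r}")
        seen.add(tid)
        reachable.append(tid)
        stack.extend(sorted(children.get(tid, []), reverse=True))

    def lineage_of(tid: str) -> list[str]:
        out: list[str] = []
        cur = parents.get(tid)
        visited = {tid}
        while cur is not None and cur != root_id:
            if cur in visited:
                raise DictionaryError(f"parent cycle involving taxon {cur!r}")
            visited.add(cur)
            out.append(names.get(cur, cur))
            cur = parents.get(cur)
        out.append(names.get(root_id, root_id))
        return out

    concepts = [
        Concept(
            concept_id=tid,
            preferred_term=names[tid],
            kind="taxon",
            category=ranks[tid],
            lineage=lineage_of(tid),
        )
        for tid in sorted(reachable)
    ]
    return Dictionary(concepts)


# ---------------------------------------------------------------------------
# Trait dictionary
# ---------------------------------------------------------------------------

_DEFAULT_TRAIT_COLUMNS = {
    "term": "term",
    "category": "category",
    "trait_type": "trait type",
    "synonyms": "synonyms",
    "source_uri": "source URI",
}


def load_trait_dictionary(
    table: Union[str, Path, pd.DataFrame],
    column_map: Optional[Mapping[str, str]] = None,
    synonym_delimiter: str = ";",
) -> Dictionary:
    """Load the curated trait dictionary from a spreadsheet or TSV.

    One concept per row; the synonyms cell is split on the delimiter,
    trimmed and de-duplicated case-insensitively (the preferred term is
    always the first surface form).  Rows with a category outside
    {feeding ecology, habitat, morphology} raise a validation error
    naming the row.
    """
    cols = dict(_DEFAULT_TRAIT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = _read_table(table).fillna("")
    lowered = {str(c).strip().casefold(): c for c in frame.columns}

    def col(key: str) -> Optional[str]:
        return lowered.get(cols[key].casefold())

    for required in ("term", "category"):
        if col(required) is None:
            raise DictionaryError(f"trait table missing column {cols[required]!r}")

    concepts: list[Concept] = []
    for i, row in enumerate(frame.to_dict("records")):
        term = str(row[col("term")]).strip()
        category = str(row[col("category")]).strip().casefold()
        if category not in TRAIT_CATEGORIES:
            raise DictionaryError(
                f"row {i}: unknown trait category {category!r} "
                f"(expected one of {TRAIT_CATEGORIES})"
            )
        trait_type = None
        if col("trait_type") is not None:
            raw = str(row[col("trait_type")]).strip().casefold()
            trait_type = raw if raw in TRAIT_TYPES else None
        raw_syn = str(row[col("synonyms")]) if col("synonyms") is not None else ""
        synonyms: list[str] = []
        seen = {normalize_surface(term)}
        for part in raw_syn.split(synonym_delimiter):
            form = part.strip()
            key = normalize_surface(form)
            if form and key not in seen:
                seen.add(key)
                synonyms.append(form)
        uri = (
            str(row[col("source_uri")]).strip()
            if col("source_uri") is not None
            else ""
        )
        concepts.append(
            Concept(
                concept_id=uri or f"trait:{i}",
                preferred_term=term,
                kind="trait",
                category=category,
                trait_type=trait_type,
                synonyms=synonyms,
                source_uri=uri or None,
            )
        )
    return Dictionary(concepts)


# ---------------------------------------------------------------------------
# Synonym curation
# ---------------------------------------------------------------------------

def corpus_token_counts(corpus: Sequence[Document]) -> Counter:
    """Case-folded whole-token unigram counts over a corpus."""
    counts: Counter = Counter()
    for doc in corpus:
        counts.update(t.casefold() for t, _ in tokenize(doc.text))
    return counts


def _ngram_count(counts_by_doc: list[list[str]], phrase_tokens: list[str]) -> int:
    n = len(phrase_tokens)
    total = 0
    for tokens in counts_by_doc:
        for i in range(len(tokens) - n + 1):
            if tokens[i : i + n] == phrase_tokens:
                total += 1
    return total


def filter_synonyms_by_frequency(
    dictionary: Dictionary,
    corpus: Sequence[Document],
    min_count: int = 10,
) -> Dictionary:
    """Drop synonyms occurring fewer than ``min_count`` times in the corpus.

    Occurrences are counted as whole-token, case-insensitive matches of
    the full synonym phrase; preferred terms are always retained.
    """
    doc_tokens = [
        [t.casefold() for t, _ in tokenize(doc.text)] for doc in corpus
    ]
    unigrams: Counter = Counter()
    for tokens in doc_tokens:
        unigrams.update(tokens)

    filtered: list[Concept] = []
    for concept in dictionary:
        kept = []
        for syn in concept.synonyms:
            phrase = normalize_surface(syn).split()
            if not phrase:
                continue
            if len(phrase) == 1:
                count = unigrams[phrase[0]]
            else:
                count = _ngram_count(doc_tokens, phrase)
            if count >= min_count:
                kept.append(syn)
        filtered.append(
            Concept(
                concept_id=concept.concept_id,
                preferred_term=concept.preferred_term,
                kind=concept.kind,
                category=concept.category,
                trait_type=concept.trait_type,
                synonyms=kept,
                lineage=list(concept.lineage),
                source_uri=concept.source_uri,
            )
        )
    return Dictionary(filtered)


def expand_plural_variants(dictionary: Dictionary) -> Dictionary:
    """Add regular plural/singular counterparts of trait surface forms.

    For each trait surface form the final word is inflected with the
    regular s/es/y→ies rules (both directions) and the counterpart added
    as a synonym when not already present.  Taxon concepts are untouched;
    irregular plurals are never generated.  Idempotent.
    """
    expanded: list[Concept] = []
    for concept in dictionary:
        if concept.kind != "trait":
            expanded.append(concept)
            continue
        forms = concept.surface_forms()
        present = {normalize_surface(f) for f in forms}
        new_synonyms = list(concept.synonyms)
        for form in forms:
            words = form.split()
            if not words:
                continue
            for variant_last in filter(None, (pluralize(words[-1]), strip_plural(words[-1]))):
                variant = " ".join(words[:-1] + [variant_last])
                key = normalize_surface(variant)
                if key not in present:
                    present.add(key)
                    new_synonyms.append(variant)
        expanded.append(
            Concept(
                concept_id=concept.concept_id,
                preferred_term=concept.preferred_term,
                kind=concept.kind,
                category=concept.category,
                trait_type=concept.trait_type,
                synonyms=new_synonyms,
                lineage=list(concept.lineage),
                source_uri=concept.source_uri,
            )
        )
    return Dictionary(expanded)
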