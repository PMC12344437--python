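"""Synthetic treatment-style corpora with planted gold annotation layers.

Generates documents that imitate the structure of taxonomic treatments —
a taxon heading sentence followed by short morphology/habitat sentences
carrying trait mentions, measurement or colour values and life-stage
qualifiers — with every planted entity recorded at its exact character
offsets and relations planted per the treatment prose structure:
arthropod→trait links are few-to-many (one taxon mention anchors the
trait mentions of the following sentences), trait→value links are
one-to-one within a sentence.

Because gold layers are exact by construction, the generated corpora
serve as the oracle for the tagging, normalisation, relation and
statistics stages.  The prose is deliberately formulaic; it does not
model the vocabulary breadth, nested clause structure or annotation
ambiguity of real treatments, so perfect scores here bound only
implementation correctness, not real-corpus performance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .dictionaries import Concept, Dictionary, expand_plural_variants
from .model import Document, EntityAnnotation, RelationAnnotation

#: toy taxon checklist: (taxonID, parent, name, status, rank)
TOY_CHECKLIST_ROWS = [
    ("RT", "", "Arthropoda", "accepted", "phylum"),
    ("C1", "RT", "Insecta", "accepted", "class"),
    ("O1", "C1", "Diptera", "accepted", "order"),
    ("F1", "O1", "Tipulidae", "accepted", "family"),
    ("G1", "F1", "Tipula", "accepted", "genus"),
    ("S1", "G1", "Tipula oleracea", "accepted", "species"),
    ("S2", "G1", "Tipula paludosa", "accepted", "species"),
    ("F2", "O1", "Culicidae", "accepted", "family"),
    ("G2", "F2", "Aedes", "accepted", "genus"),
    ("S3", "G2", "Aedes aegypti", "accepted", "species"),
    ("O2", "C1", "Hymenoptera", "accepted", "order"),
    ("F3", "O2", "Apidae", "accepted", "family"),
    ("G3", "F3", "Apis", "accepted", "genus"),
    ("S4", "G3", "Apis mellifera", "accepted", "species"),
    ("F4", "O2", "Formicidae", "accepted", "family"),
    ("G4", "F4", "Formica", "accepted", "genus"),
    ("S5", "G4", "Formica rufa", "accepted", "species"),
]

#: toy trait rows: (term, category, trait type, synonyms, uri)
TOY_TRAIT_ROWS = [
    ("femur", "morphology", "length/width", "femora", "uri:trait/femur"),
    ("wing", "morphology", "length/width", "", "uri:trait/wing"),
    ("antenna", "morphology", "count", "antennae", "uri:trait/antenna"),
    ("mesoscutum", "morphology", "yes/no", "", "uri:trait/mesoscutum"),
    ("leg", "morphology", "count", "", "uri:trait/leg"),
    ("pronotum", "morphology", "yes/no", "", "uri:trait/pronotum"),
    ("wetland", "habitat", "yes/no", "", "uri:trait/wetland"),
    ("grassland", "habitat", "yes/no", "", "uri:trait/grassland"),
    ("predator", "feeding ecology", "yes/no", "", "uri:trait/predator"),
    ("herbivore", "feeding ecology", "yes/no", "", "uri:trait/herbivore"),
]

_COLORS = ("reddish-brown", "brownish-yellow", "yellowish", "testaceous", "fuscous")
_PLAIN_ADJECTIVES = ("elongate", "slender", "robust", "flattened", "smooth")
_UNKNOWN_GENERA = ("Zorptila", "Quexilla", "Vantrixa", "Morpelia")
_FILLERS = (
    "The specimens were collected during spring.",
    "Additional material was examined from the locality.",
    "The holotype is deposited in the museum collection.",
    "Further studies will clarify this record.",
    "The original description appeared much earlier.",
    "Collecting permits were issued by the local authority.",
)


def toy_checklist_frame() -> pd.DataFrame:
    return pd.DataFrame(
        TOY_CHECKLIST_ROWS,
        columns=["taxonID", "parentNameUsageID", "scientificName",
                 "taxonomicStatus", "taxonRank"],
    )


def toy_trait_frame() -> pd.DataFrame:
    return pd.DataFrame(
        TOY_TRAIT_ROWS,
        columns=["term", "category", "trait type", "synonyms", "source URI"],
    )


def make_trait_dictionary_table(
    n_feeding: int = 81, n_habitat: int = 184, n_morphology: int = 125
) -> pd.DataFrame:
    """Synthetic stand-in for the curated trait-dictionary spreadsheet.

    Generates a table with the same column layout and category sizes as
    the curated supplementary trait list (default 81 feeding ecology,
    184 habitat, 125 morphology = 390 rows); terms are synthetic slugs,
    so the table exercises the loader and its counts, not the lexicon.
    """
    rows = []
    for category, count in (
        ("feeding ecology", n_feeding),
        ("habitat", n_habitat),
        ("morphology", n_morphology),
    ):
        slug = category.replace(" ", "-")
        for i in range(count):
            rows.append(
                (
                    f"synthetic {slug} term {i:03d}",
                    category,
                    "yes/no",
                    f"synthetic {slug} synonym {i:03d}",
                    f"uri:synthetic/{slug}/{i:03d}",
                )
            )
    return pd.DataFrame(
        rows, columns=["term", "category", "trait type", "synonyms", "source URI"]
    )


@dataclass
class SimConfig:
    """Generator conditions for one synthetic corpus.

    Default densities are the gold-corpus median annotation densities per
    1,000 characters (arthropod 4.9, trait 6.4, value 6.1); qualifiers
    are sparse.  Link rates of 1.0 plant a relation for every trait
    (to the anchoring taxon mention of its block) and every value (to
    the preceding trait in its sentence); noise rates default to 0 so
    the gold layer is exactly recoverable by the dictionary taggers.
    """

    seed: int = 0
    n_docs: int = 25
    doc_length_range: tuple[int, int] = (2000, 4000)
    density_arthropod: float = 4.9
    density_trait: float = 6.4
    density_value: float = 6.1
    density_qualifier: float = 0.4
    trait_link_rate: float = 1.0
    value_link_rate: float = 1.0
    plural_rate: float = 0.25
    unknown_taxon_rate: float = 0.0
    unlinked_value_rate: float = 0.0

    def validate(self) -> "SimConfig":
        for name in ("density_arthropod", "density_trait", "density_value",
                     "density_qualifier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("trait_link_rate", "value_link_rate", "plural_rate",
                     "unknown_taxon_rate", "unlinked_value_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.doc_length_range
        if not (0 < lo <= hi):
            raise ValueError("doc_length_range must satisfy 0 < lo <= hi")
        # a sentence is ~40 characters; each carries at most ~2 annotations
        total_density = (self.density_arthropod + self.density_trait
                         + self.density_value + self.density_qualifier)
        if total_density > 50:
            raise ValueError(
                f"infeasible config: total density {total_density}/1,000 chars "
                "cannot be realised with treatment-style sentences"
            )
        return self


@dataclass
class SyntheticCorpus:
    """A generated corpus with its toy dictionaries and provenance config."""

    docs: list[Document]
    taxa: Dictionary
    traits: Dictionary
    config: SimConfig


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.length = 0
        self.entities: list[EntityAnnotation] = []
        self.relations: list[RelationAnnotation] = []
        self._n = 0

    def add_sentence(self, text: str, spans: Sequence[tuple[int, int, str, Optional[str]]]) -> list[str]:
        """Append a sentence; ``spans`` are local (start, end, etype, concept).
        Returns the entity ids created, in span order."""
        base = self.length + (1 if self.parts else 0)
        ids = []
        for start, end, etype, concept_id in spans:
            eid = f"{self.doc_id}-e{self._n}"
            self._n += 1
            self.entities.append(
                EntityAnnotation(
                    entity_id=eid, start=base + start, end=base + end,
                    etype=etype, surface=text[start:end],
                    concept_id=concept_id, score=None,
                )
            )
            ids.append(eid)
        self.parts.append(text)
        self.length = base + len(text)
        return ids

    def build(self, split_tag: Optional[str]) -> Document:
        return Document(
            self.doc_id, " ".join(self.parts), self.entities, self.relations,
            split_tag,
        ).validate()


def _toy_dictionaries() -> tuple[Dictionary, Dictionary]:
    from .dictionaries import build_taxon_dictionary, load_trait_dictionary

    taxa = build_taxon_dictionary(toy_checklist_frame(), root_id="RT")
    traits = expand_plural_variants(load_trait_dictionary(toy_trait_frame()))
    return taxa, traits


def generate_corpus(cfg: SimConfig) -> SyntheticCorpus:
    """Generate a deterministic corpus under ``cfg``'s study conditions.

    Documents are built from blocks: a taxon anchor sentence followed by
    at most five dependent sentences (trait+value, trait-only, qualifier
    or standalone value), so planted arthropod→trait links always lie
    within a six-sentence window with the anchor as the nearest preceding
    taxon mention.  Filler sentences containing no plantable surface are
    appended to blocks to reach the target length, keeping realised
    densities within ~±20% of the configured targets.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)
    taxa, traits = _toy_dictionaries()
    species = [c for c in taxa if c.category == "species"]
    trait_concepts = list(traits)
    docs: list[Document] = []

    for d in range(cfg.n_docs):
        target_len = rng.randint(*cfg.doc_length_range)
        n_arth = max(1, round(cfg.density_arthropod * target_len / 1000))
        n_trait = round(cfg.density_trait * target_len / 1000)
        n_value = round(cfg.density_value * target_len / 1000)
        n_qual = round(cfg.density_qualifier * target_len / 1000)
        n_unlinked_value = round(n_value * cfg.unlinked_value_rate)
        n_paired = min(n_value - n_unlinked_value, n_trait)
        n_unlinked_value += (n_value - n_unlinked_value) - n_paired
        n_trait_only = n_trait - n_paired

        builder = _DocBuilder(f"synth-{cfg.seed}-{d:03d}")

        # dependent-sentence tokens, shuffled then dealt into blocks of <= 5
        tokens = (["pair"] * n_paired + ["trait"] * n_trait_only
                  + ["qual"] * n_qual + ["value"] * n_unlinked_value)
        rng.shuffle(tokens)
        n_blocks = max(n_arth, (len(tokens) + 4) // 5)
        blocks: list[list[str]] = [[] for _ in range(n_blocks)]
        for i, token in enumerate(tokens):
            blocks[i % n_blocks].append(token)
        # estimate filler need from a ~45-char mean sentence length
        est_entity_sentences = n_blocks + len(tokens)
        n_filler = max(0, round(target_len / 45) - est_entity_sentences)
        extra_anchors = max(0, n_arth - n_blocks)

        for b, block in enumerate(blocks):
            # anchor quota exhausted -> orphan block: traits stay unlinked
            anchor_id = (
                _emit_anchor(builder, rng, cfg, species) if b < n_arth else None
            )
            for token in block:
                _emit_dependent(builder, rng, cfg, trait_concepts, token, anchor_id)
            for _ in range(n_filler // n_blocks + (1 if b < n_filler % n_blocks else 0)):
                builder.add_sentence(rng.choice(_FILLERS), [])
        for _ in range(extra_anchors):
            _emit_anchor(builder, rng, cfg, species)

        docs.append(builder.build(split_tag=None))
    return SyntheticCorpus(docs=docs, taxa=taxa, traits=traits, config=cfg)


def _emit_anchor(
    builder: _DocBuilder,
    rng: random.Random,
    cfg: SimConfig,
    species: Sequence[Concept],
) -> str:
    """Taxon heading sentence; returns the anchor entity id."""
    if rng.random() < cfg.unknown_taxon_rate:
        genus = rng.choice(_UNKNOWN_GENERA)
        epithet = rng.choice(("brevis", "maculata", "rostrata", "pallida"))
        name, concept_id = f"{genus} {epithet}", None
    else:
        concept = rng.choice(sorted(species, key=lambda c: c.concept_id))
        name, concept_id = concept.preferred_term, concept.concept_id
    text = f"{name} sp. nov. is described here."
    ids = builder.add_sentence(text, [(0, len(name), "arthropod", concept_id)])
    return ids[0]


def _trait_surface(rng: random.Random, cfg: SimConfig, concept: Concept) -> str:
    forms = concept.surface_forms()
    if len(forms) > 1 and rng.random() < cfg.plural_rate:
        return rng.choice(forms[1:])
    return concept.preferred_term


def _emit_dependent(
    builder: _DocBuilder,
    rng: random.Random,
    cfg: SimConfig,
    trait_concepts: Sequence[Concept],
    token: str,
    anchor_id: Optional[str],
) -> None:
    if token == "qual":
        qual = rng.choice(("female", "male", "juvenile", "larva", "adult"))
        text = f"The {qual} specimen was examined."
        builder.add_sentence(text, [(4, 4 + len(qual), "qualifier", None)])
        return
    if token == "value":
        num = f"{rng.randint(2, 2400)}"
        text = f"Specimens occur at {num} m."
        start = text.index(num)
        builder.add_sentence(text, [(start, start + len(num) + 2, "value", None)])
        return

    concept = rng.choice(sorted(trait_concepts, key=lambda c: c.concept_id))
    surface = _trait_surface(rng, cfg, concept)
    if token == "trait":
        adjective = rng.choice(_PLAIN_ADJECTIVES)
        text = f"The {surface} is {adjective}."
        ids = builder.add_sentence(
            text, [(4, 4 + len(surface), "trait", concept.concept_id)]
        )
        trait_id, value_id = ids[0], None
    else:  # pair
        style = rng.choice(("color", "measure", "series"))
        if style == "color":
            color = rng.choice(_COLORS)
            text = f"The {surface} is {color}."
            spans = [
                (4, 4 + len(surface), "trait", concept.concept_id),
                (len(text) - 1 - len(color), len(text) - 1, "value", None),
            ]
        elif style == "measure":
            num = f"{rng.randint(1, 80)}.{rng.randint(0, 9)} mm"
            cap = surface[0].upper() + surface[1:]
            text = f"{cap} length {num}."
            spans = [
                (0, len(cap), "trait", concept.concept_id),
                (len(text) - 1 - len(num), len(text) - 1, "value", None),
            ]
        else:
            series = ", ".join(str(rng.randint(10, 60)) for _ in range(rng.randint(3, 6)))
            cap = surface[0].upper() + surface[1:]
            text = f"{cap} segments length {series}."
            spans = [
                (0, len(cap), "trait", concept.concept_id),
                (len(text) - 1 - len(series), len(text) - 1, "value", None),
            ]
        ids = builder.add_sentence(text, spans)
        trait_id, value_id = ids[0], ids[1]

    if anchor_id is not None and rng.random() < cfg.trait_link_rate:
        builder.relations.append(RelationAnnotation(anchor_id, trait_id, "hasTrait"))
    if value_id is not None and rng.random() < cfg.value_link_rate:
        builder.relations.append(RelationAnnotation(trait_id, value_id, "hasValue"))


def corpus_truth_report(corpus: SyntheticCorpus) -> dict:
    """Planted counts and densities — the oracle for downstream stages.

    Accepts only corpora produced by :func:`generate_corpus`; the report
    is recomputed from the gold layers, so it stays consistent with any
    document mutation the caller may have performed.
    """
    if not isinstance(corpus, SyntheticCorpus):
        raise TypeError(
            "corpus_truth_report only accepts a SyntheticCorpus produced by "
            "generate_corpus"
        )
    entity_counts: dict[str, int] = {}
    relation_counts: dict[str, int] = {}
    per_doc_density: dict[str, dict[str, float]] = {}
    for doc in corpus.docs:
        counts: dict[str, int] = {}
        for ann in doc.annotations:
            entity_counts[ann.etype] = entity_counts.get(ann.etype, 0) + 1
            counts[ann.etype] = counts.get(ann.etype, 0) + 1
        for rel in doc.relations:
            relation_counts[rel.rtype] = relation_counts.get(rel.rtype, 0) + 1
        per_doc_density[doc.doc_id] = {
            t: 1000.0 * c / doc.length for t, c in counts.items()
        }
    return {
        "n_docs": len(corpus.docs),
        "entity_counts": entity_counts,
        "relation_counts": relation_counts,
        "per_doc_density": per_doc_density,
        "config_seed": corpus.config.seed,
    }
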