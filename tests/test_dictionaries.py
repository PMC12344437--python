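import pandas as pd
import pytest

from treatminer.dictionaries import (
    Dictionary,
    DictionaryError,
    build_taxon_dictionary,
    expand_plural_variants,
    filter_synonyms_by_frequency,
    load_trait_dictionary,
    pluralize,
    strip_plural,
)
from treatminer.model import Document
from treatminer.synthetic import toy_checklist_frame, toy_trait_frame

TOY_ROWS = [
    ("RT", "", "Arthropoda", "accepted", "phylum"),
    ("A", "RT", "Agenus", "accepted", "genus"),
    ("B", "A", "Agenus bspecies", "accepted", "species"),
    ("C", "A", "Agenus cspecies", "synonym", "species"),
    ("D", "X", "Orphanus dspecies", "accepted", "species"),
]
COLUMNS = ["taxonID", "parentNameUsageID", "scientificName",
           "taxonomicStatus", "taxonRank"]


class TestTaxonDictionary:
    def test_empty_checklist(self):
        empty = pd.DataFrame([], columns=COLUMNS)
        assert len(build_taxon_dictionary(empty, root_id="RT")) == 0

    def test_accepted_reachable_taxa_only(self):
        d = build_taxon_dictionary(pd.DataFrame(TOY_ROWS, columns=COLUMNS), "RT")
        assert set(d.concepts) == {"A", "B"}
        assert d["B"].lineage == ["Agenus", "Arthropoda"]
        assert d["A"].lineage == ["Arthropoda"]

    def test_row_order_independence(self):
        frame = pd.DataFrame(TOY_ROWS, columns=COLUMNS)
        shuffled = frame.sample(frac=1.0, random_state=3)
        a = build_taxon_dictionary(frame, "RT")
        b = build_taxon_dictionary(shuffled, "RT")
        assert set(a.concepts) == set(b.concepts)
        assert all(a[c].lineage == b[c].lineage for c in a.concepts)

    def test_missing_column_raises_schema_error(self):
        broken = pd.DataFrame([("RT", "", "Arthropoda")],
                              columns=["taxonID", "parentNameUsageID", "scientificName"])
        with pytest.raises(DictionaryError, match="column"):
            build_taxon_dictionary(broken, "RT")

    def test_parent_cycle_detected(self):
        rows = [
            ("RT", "", "Arthropoda", "accepted", "phylum"),
            ("A", "B", "Aname", "accepted", "genus"),
            ("B", "A", "Bname", "accepted", "genus"),
        ]
        # neither A nor B is reachable from RT, so force the lineage walk
        rows.append(("E", "RT", "Ename", "accepted", "genus"))
        frame = pd.DataFrame(rows, columns=COLUMNS)
        d = build_taxon_dictionary(frame, "RT")
        assert set(d.concepts) == {"E"}


class TestTraitDictionary:
    def test_toy_table_loads_with_categories(self):
        d = load_trait_dictionary(toy_trait_frame())
        counts = d.category_counts()
        assert sum(counts.values()) == len(d)
        assert set(counts) <= {"feeding ecology", "habitat", "morphology"}

    def test_empty_synonym_cell_keeps_preferred_only(self):
        frame = pd.DataFrame(
            [("leg", "morphology", "count", "", "uri:1")],
            columns=["term", "category", "trait type", "synonyms", "source URI"],
        )
        (concept,) = load_trait_dictionary(frame)
        assert concept.surface_forms() == ["leg"]

    def test_synonyms_deduplicated_case_insensitively(self):
        frame = pd.DataFrame(
            [("limb", "morphology", "count", "leg; legs; Legs", "uri:1")],
            columns=["term", "category", "trait type", "synonyms", "source URI"],
        )
        (concept,) = load_trait_dictionary(frame)
        assert concept.synonyms == ["leg", "legs"]

    def test_unknown_category_names_row(self):
        frame = pd.DataFrame(
            [("leg", "anatomy", "count", "", "uri:1")],
            columns=["term", "category", "trait type", "synonyms", "source URI"],
        )
        with pytest.raises(DictionaryError, match="row 0"):
            load_trait_dictionary(frame)

    def test_duplicate_concept_id_rejected(self):
        frame = pd.DataFrame(
            [("leg", "morphology", "count", "", "uri:1"),
             ("wing", "morphology", "count", "", "uri:1")],
            columns=["term", "category", "trait type", "synonyms", "source URI"],
        )
        with pytest.raises(DictionaryError, match="duplicate"):
            load_trait_dictionary(frame)

    def test_surface_index_covers_all_forms(self):
        d = load_trait_dictionary(toy_trait_frame())
        indexed = set(d.exact_index)
        for concept in d:
            for form in concept.surface_forms():
                assert form in indexed

    def test_tsv_roundtrip(self, tmp_path):
        d = expand_plural_variants(load_trait_dictionary(toy_trait_frame()))
        path = tmp_path / "traits.tsv"
        d.write_tsv(path)
        back = Dictionary.read_tsv(path)
        assert set(back.concepts) == set(d.concepts)
        for cid in d.concepts:
            assert back[cid].synonyms == d[cid].synonyms
            assert back[cid].category == d[cid].category


class TestSynonymFrequencyFilter:
    def _dict(self):
        frame = pd.DataFrame(
            [("femur", "morphology", "length/width", "thighbone; femora", "uri:1")],
            columns=["term", "category", "trait type", "synonyms", "source URI"],
        )
        return load_trait_dictionary(frame)

    def _corpus(self):
        text = ("The femora were measured. " * 12) + ("Thighbone noted. " * 2)
        return [Document("d1", text)]

    def test_rare_synonym_dropped_frequent_kept(self):
        filtered = filter_synonyms_by_frequency(self._dict(), self._corpus(), 10)
        (concept,) = filtered
        assert concept.synonyms == ["femora"]
        assert concept.preferred_term == "femur"

    def test_min_count_zero_is_identity(self):
        filtered = filter_synonyms_by_frequency(self._dict(), self._corpus(), 0)
        assert filtered["uri:1"].synonyms == ["thighbone", "femora"]

    def test_empty_corpus_drops_all_synonyms(self):
        filtered = filter_synonyms_by_frequency(self._dict(), [], 10)
        assert filtered["uri:1"].synonyms == []
        assert filtered["uri:1"].preferred_term == "femur"

    def test_multiword_synonym_counted_as_phrase(self):
        frame = pd.DataFrame(
            [("wing", "morphology", "count", "fore wing", "uri:2")],
            columns=["term", "category", "trait type", "synonyms", "source URI"],
        )
        d = load_trait_dictionary(frame)
        corpus = [Document("d1", "The fore wing is long. " * 10 + "fore legs. " * 10)]
        filtered = filter_synonyms_by_frequency(d, corpus, 10)
        assert filtered["uri:2"].synonyms == ["fore wing"]


class TestPluralExpansion:
    @pytest.mark.parametrize(
        "word, plural",
        [("leg", "legs"), ("body", "bodies"), ("patch", "patches"),
         ("proboscis", None), ("tarsus", None)],
    )
    def test_pluralize_rule_table(self, word, plural):
        assert pluralize(word) == plural

    @pytest.mark.parametrize(
        "word, singular",
        [("legs", "leg"), ("bodies", "body"), ("patches", "patch"),
         ("proboscis", None), ("glass", None)],
    )
    def test_strip_plural_rule_table(self, word, singular):
        assert strip_plural(word) == singular

    def test_expansion_adds_counterparts_for_traits_only(self):
        d = expand_plural_variants(load_trait_dictionary(toy_trait_frame()))
        femur = next(c for c in d if c.preferred_term == "femur")
        assert "femurs" in femur.synonyms or "femora" in femur.synonyms
        leg = next(c for c in d if c.preferred_term == "leg")
        assert "legs" in leg.synonyms

    def test_expansion_idempotent(self):
        once = expand_plural_variants(load_trait_dictionary(toy_trait_frame()))
        twice = expand_plural_variants(once)
        for cid in once.concepts:
            assert twice[cid].synonyms == once[cid].synonyms

    def test_taxa_untouched(self):
        taxa = build_taxon_dictionary(toy_checklist_frame(), "RT")
        expanded = expand_plural_variants(taxa)
        for cid in taxa.concepts:
            assert expanded[cid].synonyms == taxa[cid].synonyms
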