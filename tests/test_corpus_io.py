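import json

import pytest

from treatminer.corpus_io import (
    FormatError,
    build_context_windows,
    build_long_range_context,
    entities_to_iob2,
    iob2_chunks,
    iob2_to_entities,
    read_bioc_collection,
    read_conll,
    sentence_index_of,
    split_sentences,
    tokenize,
    write_bioc_collection,
    write_conll,
)
from treatminer.model import (
    Document,
    EntityAnnotation,
    RelationAnnotation,
    TokenLabelSequence,
    ValidationError,
)


def _ann(eid, start, end, etype, **kw):
    return EntityAnnotation(entity_id=eid, start=start, end=end, etype=etype, **kw)


class TestBioC:
    def test_empty_collection_roundtrip(self, tmp_path):
        path = tmp_path / "empty.json"
        write_bioc_collection([], path)
        assert read_bioc_collection(path) == []

    def test_single_passage_annotation_surface(self, tmp_path):
        doc = Document("d1", "Tipula is large.", [_ann("e0", 0, 6, "arthropod")])
        path = tmp_path / "one.json"
        write_bioc_collection([doc], path)
        (loaded,) = read_bioc_collection(path)
        assert loaded.annotations[0].surface == "Tipula"

    def test_multi_passage_offsets_rebased(self, tmp_path):
        """A passage-local span rebases across earlier passages plus the
        single-newline separators."""
        collection = {
            "documents": [
                {
                    "id": "d1",
                    "passages": [
                        {"offset": 0, "text": "x" * 20, "annotations": []},
                        {
                            "offset": 21,
                            "text": "Aedes aegypti bites",
                            "annotations": [
                                {
                                    "id": "e0",
                                    "infons": {"type": "arthropod"},
                                    "text": "Aedes",
                                    "locations": [{"offset": 0, "length": 5}],
                                }
                            ],
                        },
                    ],
                }
            ]
        }
        path = tmp_path / "multi.json"
        path.write_text(json.dumps(collection))
        (doc,) = read_bioc_collection(path)
        ann = doc.annotations[0]
        assert (ann.start, ann.end) == (21, 26)
        assert doc.text[21:26] == "Aedes"

    def test_roundtrip_lossless(self, tmp_path, small_corpus):
        path = tmp_path / "corpus.json"
        docs = small_corpus.docs
        write_bioc_collection(docs, path)
        loaded = read_bioc_collection(path)
        assert len(loaded) == len(docs)
        for orig, back in zip(docs, loaded):
            assert back.doc_id == orig.doc_id
            assert back.text == orig.text
            assert back.split_tag == orig.split_tag
            orig_set = {
                (a.start, a.end, a.etype, a.concept_id)
                for a in orig.annotations
            }
            back_set = {
                (a.start, a.end, a.etype, a.concept_id)
                for a in back.annotations
            }
            assert back_set == orig_set
            assert {(r.head, r.tail, r.rtype) for r in back.relations} == {
                (r.head, r.tail, r.rtype) for r in orig.relations
            }

    def test_qualifier_and_relation_survive(self, tmp_path):
        doc = Document(
            "d1",
            "Tipula female specimen.",
            [_ann("a", 0, 6, "arthropod"), _ann("q", 7, 13, "qualifier")],
            [RelationAnnotation("a", "q", "hasQualifier")],
        )
        path = tmp_path / "q.json"
        write_bioc_collection([doc], path)
        (back,) = read_bioc_collection(path)
        assert back.annotations[1].etype == "qualifier"
        assert back.relations[0].rtype == "hasQualifier"

    def test_malformed_json_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(FormatError):
            read_bioc_collection(path)

    def test_out_of_range_offset_names_document(self, tmp_path):
        collection = {
            "documents": [
                {
                    "id": "bad-doc",
                    "passages": [
                        {
                            "offset": 0,
                            "text": "short",
                            "annotations": [
                                {
                                    "id": "e0",
                                    "infons": {"type": "trait"},
                                    "text": "",
                                    "locations": [{"offset": 3, "length": 40}],
                                }
                            ],
                        }
                    ],
                }
            ]
        }
        path = tmp_path / "oor.json"
        path.write_text(json.dumps(collection))
        with pytest.raises(ValidationError, match="bad-doc"):
            read_bioc_collection(path)


class TestTokenizeAndSentences:
    def test_decimal_and_hyphen_kept_whole(self):
        tokens = [t for t, _ in tokenize("Femur 56.6 mm, brownish-yellow.")]
        assert "56.6" in tokens
        assert "brownish-yellow" in tokens
        assert "," in tokens and "." in tokens

    def test_punctuation_peeled_with_correct_spans(self):
        text = '(legs), "wing".'
        for surface, (s, e) in tokenize(text):
            assert text[s:e] == surface

    def test_two_sentences(self):
        assert len(split_sentences("First. Second.")) == 2

    def test_genus_abbreviation_guarded(self):
        spans = split_sentences("T. oleracea is large. Length 5 mm.")
        assert len(spans) == 2
        s, e = spans[0]
        assert "T. oleracea is large." == "T. oleracea is large. Length 5 mm."[s:e]

    def test_guard_list_abbreviation(self):
        assert len(split_sentences("Tipula sp. Nov is not split here.")) == 1

    def test_empty_text(self):
        assert split_sentences("   ") == []

    def test_spans_cover_non_whitespace(self, small_corpus):
        for doc in small_corpus.docs[:3]:
            spans = split_sentences(doc)
            covered = set()
            for s, e in spans:
                assert not doc.text[s:e] != doc.text[s:e].strip()
                covered.update(range(s, e))
            for i, ch in enumerate(doc.text):
                if not ch.isspace():
                    assert i in covered
            # ordered and non-overlapping
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestIOB2:
    def test_no_entities_all_outside(self):
        doc = Document("d", "Nothing here at all.")
        (seq,) = entities_to_iob2(doc)
        assert set(seq.labels) == {"O"}

    def test_entity_tokens_labelled(self):
        doc = Document(
            "d", "Tipula oleracea flies fast.", [_ann("e0", 0, 15, "arthropod")]
        )
        (seq,) = entities_to_iob2(doc)
        assert seq.labels == ["B-Arthropod", "I-Arthropod", "O", "O", "O"]

    def test_partial_token_span_expands_to_whole_token(self):
        doc = Document("d", "Tipula flies.", [_ann("e0", 0, 3, "arthropod")])
        (seq,) = entities_to_iob2(doc)
        assert seq.labels[0] == "B-Arthropod"
        recovered = iob2_to_entities([seq])
        assert recovered[0].span == (0, 6)

    def test_overlapping_entities_rejected(self):
        doc = Document(
            "d",
            "mesoscutum setae",
            [_ann("a", 0, 16, "trait"), _ann("b", 11, 16, "trait")],
        )
        with pytest.raises(ValidationError, match="merge"):
            entities_to_iob2(doc)

    def test_chunks_from_labels(self):
        seq = TokenLabelSequence(
            [("a", (0, 1)), ("b", (2, 3)), ("c", (4, 5)), ("d", (6, 7))],
            ["B-Trait", "I-Trait", "O", "B-Value"],
        )
        ents = iob2_to_entities([seq])
        assert [(e.etype, e.span) for e in ents] == [
            ("trait", (0, 3)),
            ("value", (6, 7)),
        ]

    def test_orphan_inside_promoted(self):
        seq = TokenLabelSequence([("x", (0, 1)), ("y", (2, 3))], ["I-Trait", "O"])
        (ent,) = iob2_to_entities([seq])
        assert ent.etype == "trait" and ent.span == (0, 1)

    def test_type_switch_starts_new_chunk(self):
        assert iob2_chunks(["B-Trait", "I-Value"]) == [
            (0, 0, "Trait"),
            (1, 1, "Value"),
        ]

    def test_roundtrip_recovers_entity_multiset(self, small_corpus):
        """Token-aligned, non-overlapping entities survive the IOB2
        projection exactly."""
        for doc in small_corpus.docs:
            recovered = iob2_to_entities(entities_to_iob2(doc))
            assert {(e.start, e.end, e.etype) for e in recovered} == {
                (a.start, a.end, a.etype) for a in doc.annotations
            }

    def test_conll_file_roundtrip(self, tmp_path, small_corpus):
        doc = small_corpus.docs[0]
        seqs = entities_to_iob2(doc)
        path = tmp_path / "doc.conll"
        write_conll(seqs, path)
        back = read_conll(path)
        assert [s.labels for s in back] == [s.labels for s in seqs]
        assert [[t for t, _ in s.tokens] for s in back] == [
            [t for t, _ in s.tokens] for s in seqs
        ]


class TestContextWindows:
    def _doc(self):
        # 10 one-word-ish sentences; arthropod in s0, traits in s1 and s8
        sentences = ["Tipula rests."] + [f"Word{i} here." for i in range(1, 10)]
        text = " ".join(sentences)
        t1 = text.index("Word1")
        t8 = text.index("Word8")
        return Document(
            "d",
            text,
            [
                _ann("a", 0, 6, "arthropod"),
                _ann("t1", t1, t1 + 5, "trait"),
                _ann("t8", t8, t8 + 5, "trait"),
            ],
            [RelationAnnotation("a", "t1", "hasTrait")],
        )

    def test_same_window_labels_from_gold(self):
        windows = build_context_windows(self._doc(), max_sentences=6)
        labels = {(w.sentence_range, w.label) for w in windows}
        assert ((0, 1), "hasTrait") in labels

    def test_distance_bound_excludes_far_pairs(self):
        windows = build_context_windows(self._doc(), max_sentences=6)
        # arthropod (s0) to trait (s8) spans 9 sentences -> no window
        assert all(w.sentence_range != (0, 8) for w in windows)

    def test_window_count_matches_brute_force(self, small_corpus):
        for doc in small_corpus.docs[:3]:
            sentences = split_sentences(doc)
            expected = 0
            typed = {("arthropod", "trait"), ("trait", "value"),
                     ("arthropod", "qualifier")}
            for h in doc.annotations:
                for t in doc.annotations:
                    if h is t or (h.etype, t.etype) not in typed:
                        continue
                    si = sentence_index_of(sentences, h.start)
                    sj = sentence_index_of(sentences, t.start)
                    if abs(si - sj) + 1 <= 6:
                        expected += 1
            windows = build_context_windows(doc, max_sentences=6)
            assert len(windows) == expected
            positives = sum(1 for w in windows if w.label != "none")
            assert positives == len(doc.relations)

    def test_rebased_offsets_slice_to_surfaces(self, small_corpus):
        doc = small_corpus.docs[0]
        for w in build_context_windows(doc):
            assert w.head_surface()
            assert w.tail_surface()
            assert w.head_surface() in doc.text
            assert (w.sentence_range[1] - w.sentence_range[0] + 1) <= 6


class TestLongRangeContext:
    def _doc(self, gap):
        head_s = "Tipula oleracea"
        tail_s = "femur"
        text = head_s + ("x" * gap) + tail_s + "y" * 300
        return (
            Document("d", text),
            _ann("h", 0, len(head_s), "arthropod"),
            _ann("t", len(head_s) + gap, len(head_s) + gap + len(tail_s), "trait"),
        )

    def test_flank_truncated_at_document_start(self):
        doc, head, tail = self._doc(gap=2000)
        window = build_long_range_context(doc, head, tail, flank=100)
        # head sits at offset 0 -> its left flank is empty
        assert window.head_offset[0] == 0

    def test_distant_pair_context_length_arithmetic(self):
        doc, head, tail = self._doc(gap=2000)
        sep = "\n"
        window = build_long_range_context(doc, head, tail, flank=100, separator=sep)
        head_len, tail_len = 15, 5
        # head slice truncated left: 0..head_end+50; tail slice full flank
        expected = (head_len + 50) + len(sep) + (tail_len + 100)
        assert len(window.text) == expected
        assert window.head_surface() == "Tipula oleracea"
        assert window.tail_surface() == "femur"

    def test_nearby_pair_single_merged_slice(self):
        doc, head, tail = self._doc(gap=100)
        window = build_long_range_context(doc, head, tail, flank=500)
        assert "\n" not in window.text
        assert window.head_surface() == "Tipula oleracea"
        assert window.tail_surface() == "femur"

    def test_identical_pair_rejected(self):
        doc, head, _ = self._doc(gap=100)
        with pytest.raises(ValidationError):
            build_long_range_context(doc, head, head)

    def test_length_bound_invariant(self, small_corpus):
        doc = small_corpus.docs[0]
        ents = doc.annotations
        head = next(e for e in ents if e.etype == "arthropod")
        max_len = max(len(e) for e in ents)
        for tail in [e for e in ents if e.etype == "trait"][:5]:
            w = build_long_range_context(doc, head, tail, flank=200)
            assert len(w.text) <= 2 * (200 + max_len) + 1
            assert w.head_surface() == doc.text[head.start:head.end]
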