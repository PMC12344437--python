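# treatminer

Desk-scale text mining of **organismal traits from taxonomic treatments** —
the structured sections of biodiversity publications that name and describe
species. Given treatment-style prose, the toolkit recognises typed entity
spans (**arthropod** taxa, **traits**, **values**, life-stage **qualifiers**),
links them to taxon and trait dictionaries (named entity normalisation), and
constructs and scores the directed relations *hasTrait* (arthropod → trait)
and *hasValue* (trait → value). It is written for biodiversity-informatics
practitioners who want a fully deterministic, inspectable baseline workflow —
dictionary gazetteers, pattern grammars and a proximity heuristic — with
transformer-based taggers and relation classifiers kept behind a plugin
contract and a JSON exchange format rather than bundled.

## What it computes

* **NER / NEN.** A greedy longest-match gazetteer over a taxon dictionary
  (built from a Darwin-Core checklist: all accepted taxa below a root, with
  their ascending lineages) and a curated trait dictionary (390-term style
  table with feeding-ecology / habitat / morphology categories and synonyms).
  Linking is tiered flexible matching: exact → case-folded →
  whitespace-collapsed → plural-stripped, over preferred terms and synonyms.
* **Relation data and baseline.** Candidate pairs from sentence context
  windows (default ≤ 6 sentences), none-class balancing (NCB), inline XML
  entity tags, long-range merged character contexts, and a proximity
  predictor (value → nearest preceding in-sentence trait; trait → nearest
  taxon mention in range).
* **Evaluation.** Strict (exact span + type) and CoNLL-style (IOB2 chunk
  match with lenient repair) entity metrics, relation metrics, with per-type
  precision P, recall R, F1 = 2PR/(P+R), and macro / support-weighted
  aggregates.
* **Agreement.** Cohen's κ = (p_o − p_e)/(1 − p_e) between two annotators'
  layers, under exact or tolerance-based partial span matching (default
  4 characters per boundary).
* **Statistics.** Annotation densities per 1,000 characters, corpus totals,
  train/test split bookkeeping.
* **Synthetic corpora.** A seeded generator that plants gold entities and
  relations at configurable densities, used as the oracle for every stage.

## Worked example

```python
from treatminer import (SimConfig, generate_corpus, tag_document,
                        strict_entity_eval, predict_proximity_relations,
                        relation_eval, resolve_relations)
from treatminer.model import Document
from treatminer.stats import corpus_summary, density_medians

corpus = generate_corpus(SimConfig(seed=7, n_docs=25))
print(corpus.docs[0].text[:120])

summary = corpus_summary(corpus.docs)
print("entities:", summary.entity_totals)
print("median density:", {k: round(v, 1)
                          for k, v in density_medians(corpus.docs).items() if v})

gold = {d.doc_id: d.annotations for d in corpus.docs}
pred = {d.doc_id: tag_document(d, corpus.taxa, corpus.traits).annotations
        for d in corpus.docs}
print("strict NER:", strict_entity_eval(gold, pred).rounded()["macro"])
```

prints

```
Apis mellifera sp. nov. is described here. The antenna is brownish-yellow. Antenna length 7.3 mm. The holotype is deposi
entities: {'arthropod': 357, 'trait': 465, 'value': 444, 'qualifier': 27}
median density: {'arthropod': 5.2, 'trait': 6.8, 'value': 6.5, 'qualifier': 0.4, 'hasTrait': 6.8, 'hasValue': 6.5}
strict NER: {'P': 1.0, 'R': 1.0, 'F': 1.0, 'support': 1293}
```

The generated corpus plants taxon mentions at ~4.9, traits at ~6.4 and
values at ~6.1 annotations per 1,000 characters (the gold-corpus medians the
generator is calibrated to); on this noise-free corpus the gazetteer and
pattern taggers recover the planted layer exactly, so strict F1 is 1.0 —
a correctness check, not a claim about real treatments (see
`docs/methods.md`). The proximity baseline likewise recovers every planted
relation (`relation_eval` reports recall 1.0 for hasTrait and hasValue).

The same workflow runs from the shell:

```bash
treatminer simulate --seed 7 --n-docs 25 --out runs/demo
treatminer tag --in runs/demo/corpus.bioc.json \
               --taxa runs/demo/taxa.tsv --traits runs/demo/traits.tsv \
               --out runs/demo/tagged.bioc.json
treatminer run --config pipeline.yaml   # full staged pipeline
```

## Layout

```
src/treatminer/
  model.py          # Document / EntityAnnotation / RelationAnnotation types
  corpus_io.py      # BioC JSON, CoNLL/IOB2, sentences, context windows
  dictionaries.py   # taxon checklist + trait table dictionaries
  tagging.py        # gazetteer, value patterns, qualifiers, overlap merge
  normalization.py  # tiered entity linking + mapping/coverage summaries
  relations.py      # candidates, NCB, inline tags, proximity baseline
  evaluation.py     # strict / conll / relation metrics
  agreement.py      # Cohen's kappa with span tolerance
  stats.py          # densities and corpus summaries
  synthetic.py      # seeded gold-corpus generator
  cli.py            # click CLI + staged pipeline runner
```
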