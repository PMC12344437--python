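# Methods

This note documents the models, conventions and design choices behind
treatminer, in the order the workflow runs.

## Annotation model

A **Document** is plain text with character-offset annotation layers;
offsets are 0-based, half-open `[start, end)`, over Unicode code points.
The entity schema has four types — `arthropod` (taxon mention), `trait`,
`value`, `qualifier` (life-stage/sex modifier) — and the relation schema is
fixed by entity typing: arthropod→trait is `hasTrait`, trait→value is
`hasValue`, arthropod→qualifier is `hasQualifier`; `none` marks an unlinked
candidate pair. BioC JSON is the interchange format. When a BioC document
has several passages they are concatenated with a single `"\n"` separator
and passage-local annotation offsets are rebased to the concatenated text;
files written by this package use one passage per document, so the
round-trip is exact byte-for-byte on text, spans, types, concept ids and
relations.

## Text segmentation

The tokenizer splits on whitespace and then peels leading/trailing
punctuation (`.,;:()[]"'—`) into separate tokens; internal periods and
hyphens never split, so decimals ("56.6") and compounds
("brownish-yellow") are single tokens. The sentence splitter is
rule-based — a `[.!?]` run followed by whitespace and a capital, digit,
quote or bracket — with a guard list for taxonomic and common
abbreviations (single-capital genus initials "T.", "sp.", "nov.", "cf.",
"e.g.", "Fig.", …) and additional breaks at newlines. Sentence spans are
trimmed to non-whitespace and partition the non-whitespace text. Both
choices are deliberate simplifications: treatment prose is telegraphic and
mostly well punctuated, and a trainable splitter would add a model
dependency without changing any downstream contract.

## IOB2 / CoNLL conversion

Entities project onto token labels with `B-`/`I-` prefixes
(`B-Arthropod`, `I-Trait`, …); a token intersecting an entity takes that
entity's label even when the character span starts or ends inside the
token (label granularity is the token; character truth stays in the
annotation layer). Overlapping entities must be merged first. The inverse
direction repairs ill-formed sequences with conlleval-compatible
semantics: an orphan `I-X` (at sequence start, after `O`, or after a
different type) opens a new chunk. For non-overlapping, token-aligned
entities the round-trip recovers the exact entity multiset; this is
property-tested on generated corpora.

## Dictionaries

**Taxa** come from a Darwin-Core-style checklist (`taxonID`,
`parentNameUsageID`, `scientificName`, `taxonomicStatus`, `taxonRank`).
Only rows with the configured accepted status (default `accepted`)
participate, both as concepts and as tree links — a non-accepted parent
breaks the path, so its subtree is unreachable from the root. Each concept
stores its ascending lineage of *names* (ending with the root's name);
output is independent of row order, and parent cycles raise an error.

**Traits** load from a curated table (term, category, trait type,
synonyms, source URI) with categories restricted to feeding ecology /
habitat / morphology and types to yes/no, association, measurement,
length/width, count. Synonym cells are split, trimmed and de-duplicated
case-insensitively; the concept id is the source URI.

**Surface index.** Lookup is tiered: exact raw form, then case-folded +
whitespace-collapsed, then plural-stripped (final word). Single-word
capitalised taxon names (genus and higher ranks) are indexed
case-sensitively only — capitalisation is informative for scientific names
and common-word collisions (e.g. a genus spelled like an English noun)
otherwise produce false hits. Trait surfaces are case-insensitive
throughout.

**Synonym curation.** `filter_synonyms_by_frequency` keeps a synonym only
if its whole-token, case-insensitive phrase count across a reference
corpus reaches the threshold (default 10) — substring hits do not count,
since the intent is to keep words actually used in treatments. Preferred
terms always survive. `expand_plural_variants` adds regular plural /
singular counterparts of the final word of each trait surface
(s / es / y→ies in both directions). Words ending in `-is`, `-us` or
`-ss` are skipped in both directions: latinate inflection (proboscis,
tarsus) is irregular and belongs in the curated synonyms column. The
expansion is idempotent and never touches taxon concepts.

## Entity recognition

The **gazetteer tagger** scans token n-grams greedily, longest first (the
n-gram cap is the longest dictionary term), through the tiered index; a
hit emits an entity with the dictionary's kind, the concept id (smallest
id on ambiguity) and score 1.0, and scanning resumes after the match —
so "Tipula oleracea" wins over "Tipula".

The **value grammar** recognises, in overlap-resolved longest-first
order: comma-separated numeric series ("38, 47, 43, 41"), number+unit
measurements with an optional range ("56.6 mm", "3–5 mm", "12 %"; unit
lexicon mm/cm/µm/m/km/mg/g/kg/%), bare numbers anchored by a preceding
measurement keyword (length, width, height, depth, size, diameter), and
colour descriptors including hyphenated compounds ("brownish-yellow")
from a closed colour lexicon. Bare place names ("China") are genuine
values in the annotation schema but are *not* tagged: no location
gazetteer ships with the package, and this gap is intentional scope.

**Qualifiers** use a closed lexicon (female, male, juvenile, larva,
adult, nymph, pupa, and their plurals).

**Overlap resolution** across layers: longer span wins; equal lengths
resolve by type precedence arthropod > trait > value > qualifier, then by
leftmost start. The result is overlap-free and independent of input
order. Model-based taggers implement the `TaggerPlugin` protocol
(`name`, `tag(doc) -> annotations` with scores in [0, 1]) and
interoperate through BioC JSON; the package never bundles trained
weights.

## Normalisation summaries

`summarize_normalization` reports m (entities of a kind), k (linked to a
concept id) and 100·k/m; trait-category breakdowns are attributed only
after successful linking, because the recogniser alone does not know a
trait's category. `dictionary_coverage` reports n (dictionary size),
l (distinct concepts observed) and 100·l/n, printing n explicitly so the
denominator is never ambiguous. Percentages round to one decimal by
default, with an integer mode (`precision=0`) for summary figures quoted
as whole percents; empty inputs report 0 by convention.

## Relation extraction data

Candidates are all schema-typed entity pairs whose mentions co-occur
within the sentence-window bound (default 6); each candidate's window is
the **minimal contiguous sentence range** covering both entities, and the
label is the gold relation type when the document links the pair, else
`none` — candidate generation thus produces the negative class a
classifier trains on. Three training-configuration transforms:

* **NCB (none-class balancing):** `none` candidates are down-sampled,
  uniformly at random under the given seed, to the count of the most
  frequent positive label, corpus-wide; positives are untouched, and with
  no positives no `none` survives.
* **Tag:** head and tail are wrapped inline as
  `<head type="…">…</head>` / `<tail type="…">…</tail>`; stripping the
  tags recovers the window text exactly (property-tested), and
  overlapping head/tail spans are rejected.
* **Long-range:** each entity is excised with `flank` surrounding
  characters *in total* (half before, half after, clipped at document
  bounds; default 500, i.e. 250 per side), and the two slices are merged
  when they touch or joined with a separator otherwise. With this
  convention the context length is bounded by
  2·(flank + entity length) + separator length.

The **proximity baseline** is a deterministic stand-in for a trained
relation classifier: each value links to the nearest preceding trait in
its sentence (values in treatments overwhelmingly follow their trait
within the sentence), and each trait links to the nearest taxon mention
within the window bound, preferring preceding mentions (treatment
headings name the taxon once, then describe it). One head per tail; only
schema-consistent relations are emitted.

## Evaluation

Two entity modes, exposed separately because they answer different
questions. **Strict**: a prediction is a true positive iff character span
and type match a gold annotation exactly, matched one-to-one per
document. **CoNLL**: chunks extracted from IOB2 label sequences (with the
lenient repair above) match on token range and type, so within-token
boundary differences are forgiven. On well-formed, token-aligned layers
the two coincide — an equivalence the test suite asserts. Relation
scoring requires head span, tail span and type to all match, with `none`
participating as a label so negative-class performance is visible.

Conventions: any metric with a zero denominator is 0; macro-F is the
unweighted mean of per-type F1 values (not the harmonic mean of macro-P
and macro-R), which keeps per-type and aggregate rows mutually
consistent; weighted aggregates use gold support; report rounding is two
decimals.

## Inter-annotator agreement

Spans from two annotators are aligned one-to-one, greedily by increasing
combined boundary distance (ties: earlier start, then input order).
Exact mode requires identical spans; partial mode tolerates up to
`tolerance` characters **per boundary** (default 4). Agreement units are
the alignment products: a matched pair contributes its two labels, an
unmatched annotation contributes its label against `none`. Cohen's
κ = (p_o − p_e)/(1 − p_e) is computed from the resulting contingency
table. No synthetic true-negative mass is added — the `(none, none)`
cell is structurally empty — which makes these κ values conservative
relative to token-level unitisations and comparable only within this
convention; this is stated prominently because κ depends on the
unitisation more than on anything else. Relations align by endpoint
spans (both boundaries of both endpoints within tolerance) regardless of
type, so a pair linked by both annotators with different types is a
disagreement unit. κ is reported per document, plus a pooled-corpus κ
from the summed tables; κ is symmetric in the annotators, and
2·matched + unmatched_a + unmatched_b = |a| + |b| always.

## Statistics

Densities are 1000 · count / document length per entity and relation
type; zero-length documents are rejected. Quantiles use numpy's
linear-interpolation convention. The train/test split ratio is
100 · (train annotations) / (test annotations), counting entities and
relations together — the convention under which a 1,453 / 7,711 split
reads as 18.8%.

## Synthetic corpus generator

The generator emulates the structure of treatment prose, not its
language. Documents are built from **blocks**: a taxon heading sentence
("*Apis mellifera* sp. nov. is described here.") followed by at most
five dependent sentences drawn from templates — trait+colour
("The antenna is brownish-yellow."), trait+measurement
("Antenna length 7.3 mm."), trait+numeric series, trait-only, qualifier,
and standalone elevation values — plus filler sentences containing no
plantable surface. Every planted mention is recorded at its exact
offsets; hasTrait relations link each trait to its block's anchor (so
gold links are always the nearest preceding taxon mention within a
six-sentence window — few-to-many, as in real treatments where one
heading anchors a dense description), and hasValue relations are
one-to-one within a sentence.

Defaults are the study conditions the package is calibrated to: 25
documents; per-1,000-character densities of 4.9 arthropod, 6.4 trait,
6.1 value (the gold-corpus medians) and 0.4 qualifier; link rates 1.0;
plural-variant rate 0.25 (exercises the plural tier without breaking
recall, since the toy dictionaries carry the plural forms); unknown-taxon
and unlinked-value rates 0. Document lengths default to 2,000–4,000
characters — a deliberate desk-scale choice versus the ~15,000-character
median of real treatment articles, keeping every stage's tests fast
while leaving blocks long enough to exercise multi-sentence windows.
Filler counts are estimated from a ~45-character mean sentence length,
which realises densities a few percent above target; the generator's
contract is ±20% on documents of ≥ 2,000 characters, and the acceptance
suite checks realised medians against that band. Generation is fully
deterministic under the seed.

What passing tests on these corpora show: that every conversion, tagger,
linker, candidate builder and metric is implemented correctly — on a
corpus where every surface is a dictionary or pattern form, strict F1 of
1.0 is a correctness identity, not a performance claim. What they do not
show: robustness to the vocabulary breadth, boundary ambiguity,
discontinuous traits and annotator disagreement of real treatments, where
trained models and curated gold data are needed.

The curated 390-term trait table is not redistributable with the
package; `make_trait_dictionary_table` generates a synthetic stand-in
with the same column layout and category sizes (81 feeding ecology,
184 habitat, 125 morphology) so the loader and its category accounting
are exercised end to end. Its terms are labelled synthetic slugs, not a
usable trait lexicon.

## Pipeline and reproducibility

The CLI wires the stages (simulate → tag → normalize → candidates →
predict → eval → agree → stats) over a working directory of BioC JSON
artifacts. Every run writes a log with the configuration hash and seeds;
identical configurations produce byte-identical artifacts. Exit codes:
0 ok, 2 validation, 3 missing upstream artifact, 4 I/O.

## Known limitations

* No abbreviation expansion of genus initials ("T. oleracea" is not
  resolved to "Tipula oleracea"), no location gazetteer for place-name
  values, no discontinuous entities.
* The gazetteer is both recogniser and normaliser; when an external
  model tagger is plugged in, its spans are re-linked by the same tiers,
  and disagreements between model type and dictionary kind are not
  adjudicated.
* Kappa values are unit-convention-dependent (see above) and should not
  be compared against token-level figures from other tools.
* The plural rules are regular-English only; irregular and latinate
  plurals must be supplied as curated synonyms.
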