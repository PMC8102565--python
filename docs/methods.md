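# Methods

## The task

Given a chemical equation written as a reaction SMILES —
`precursors>>products`, with `.` separating molecules and reactants,
reagents and solvents deliberately merged into one precursor list — the
package predicts the ordered sequence of experimental actions (ADD,
STIR, FILTER, ...) needed to execute the reaction in batch organic
synthesis. Two property families are restricted to make the learning
problem tractable:

* **Compound references.** Wherever a named compound corresponds to a
  molecule of the equation, the name is replaced by a positional token:
  `$k$` for the k-th precursor, `$-k$` for the k-th product (both
  1-based, over the alphabetically sorted canonical SMILES of each
  side). Names absent from the equation survive only if they are on a
  configurable common-reagents whitelist (water, brine, ethanol, ...).
* **Conditions.** Temperatures, durations, and pH values are binned
  into predefined half-open intervals named by tokens (`#k#`, `@k@`,
  `%k%`) with one representative value per interval. Reported condition
  values are noisy ("overnight", "about 25 C"); intervals carry the
  experimentally meaningful information and shrink the output
  vocabulary.

The serialized action text (clauses joined by `"; "`) is lossless: it
parses back into exactly the typed action objects it was rendered from.
That invariant is what allows a text-generating model to produce
machine-executable procedures, and it is property-tested on 10^4 random
sequences.

## Condition token tables

Tables are configuration (`data/condition_tokens.yaml`), not code.
Defaults:

| kind        | boundaries                                   | representatives          |
|-------------|----------------------------------------------|--------------------------|
| temperature | (-inf, -60, -10, 10, 40, 80, 120, +inf) degC | -78, -30, 0, 25, 60, 100, 150 |
| duration    | (0, 30 min, 3 h, 10 h, 48 h, +inf)           | 10 min, 1 h, 8 h, 1 day, 3 days |
| pH          | (-inf, 3, 6, 8, 11, +inf)                    | 1, 5, 7, 9, 13           |

Intervals are low-inclusive (`[lo, hi)`) so every value has a unique
token. The anchored assignments 10 min -> `@1@`, 1 h -> `@2@`,
8 h -> `@3@`, 1 day -> `@4@`, 25 degC -> `#4#` all hold simultaneously.
Phrase defaults: overnight = 16 h, over the weekend = 64 h, RT/ambient =
25 degC. "Reflux temperature" carries no token — the Reflux action
already implies it. The number of intervals beyond the anchored ones is
a package default, as is the `%k%` glyph for pH tokens; both are
isolated in the config file.

## Compound-name handling

Matching extracted names to molecules takes three layers:

1. **Stripping** removes state, concentration, temperature, and ratio
   qualifiers and splits multi-compound constructions ("1.0 M DCM
   solution of boron tribromide" -> DCM + boron tribromide). The rules
   are data — a packaged line-oriented file of `split`/`remove` regexes
   applied in order — so site-specific conventions can be swapped in
   without code changes.
2. **Normalization** maps names into a space where OCR variants
   coincide, in this order: subscript digits to ASCII, confusable
   characters unified (uppercase I and digit 1 to lowercase l, digit 0
   to uppercase O), lowercasing, spelled-out Greek letters to Greek
   characters (standalone words only, so "sulfoxide" is untouched; this
   runs while dashes still delimit words), dash/prime removal, space
   removal, special-character removal ({⋅ × · ∙ •} by default). The
   function is total and idempotent; normalized names need not be real
   names — only equality matters.
3. **Modal maps** built from observed (name, SMILES) pairs give each
   normalized name its most frequent canonical SMILES and each SMILES
   its most frequent raw name, which yields a canonical synonym per
   compound (dimethyl sulfoxide -> CS(C)=O -> DMSO). Ties break on the
   lexicographically smaller value so the maps are order-invariant.

## Dataset pipeline

Raw records (equation + extracted actions with names, raw condition
strings and quantities + record-local name map + language flag) pass
through stages in operational order; each rejected record is counted
under exactly one category, and `retained + Σ rejected = input` is
asserted on every run:

1. language filter (non-English records are dropped);
2. equation standardization: canonicalize (RDKit), deduplicate, sort
   byte-wise; empty side, unparseable molecule, or a molecule on both
   sides rejects the record;
3. action filtering: any FollowOtherProcedure or InvalidAction, fewer
   than five actions, or multiple Yield actions interlaid with
   non-work-up actions (the signature of a multi-step paragraph). The
   work-up vocabulary is {Purify, Recrystallize, Filter, Wash, Extract,
   DrySolution, DrySolid, Concentrate, CollectLayer, Yield}. When a
   record violates several rules at one stage, the category earlier in
   the taxonomy wins;
4. postprocessing: drop NoAction; merge a duration-bearing Wait into
   the preceding duration-capable action; infer missing Filter phases
   from neighbors (followed by Concentrate/Extract or preceded by
   DrySolution -> filtrate; followed by Recrystallize/DrySolid or Yield
   within two actions -> precipitate; otherwise filtrate, the majority
   class); resolve "same temperature" backwards; expand a leading
   MakeSolution into Adds; delete quantities; force single repetitions;
   drop non-vacuum atmospheres;
5. condition tokenization (failures reject under duration/temperature
   extraction errors);
6. compound substitution as described above, with the record-local map
   taking precedence over the global maps; if exactly one equation
   molecule and one extracted name remain unmapped they are matched to
   each other; otherwise any leftover rejects the record;
7. deduplication on the serialized reaction SMILES, keeping one record
   per equation by a seeded uniform draw.

Every retained pair is valid by construction: the action text parses
and references every equation molecule.

## Predictors

**Nearest neighbor.** One fingerprint per training pair; a query returns
the action text of the closest training reaction with the same precursor
count (so positional tokens transfer structurally), with an optional
stricter switch that also matches product counts. The packaged
fingerprint concatenates hashed Morgan count vectors (radius 3, 1024
bins per side) of the precursor and product sides. Concatenation was
chosen over the product-minus-precursor difference because difference
vectors cancel shared substructures and collide on homologous reaction
pairs; radius 3 is needed to separate regiochemical swaps (e.g. which
of two rings carries a methoxy vs a cyano group) that radius-2
environments cannot see. The vectorizer is pluggable, so a learned
reaction fingerprint can replace the structural one. Search is exact
(Euclidean) with ties broken by training-record id; an approximate
index can be added as an accelerator but exhaustive search is the
reference. Empty buckets fall back to the nearest available count.

**Transformer.** Procedure prediction is cast as translation from
tokenized reaction SMILES to action text. Because no deep-learning
framework is assumed, the package ships a compact reverse-mode autodiff
core on NumPy and a pre-norm transformer encoder-decoder (sinusoidal
positions, 8-head scaled dot-product attention, ReLU feed-forward,
Adam with warmup, gradient accumulation, label smoothing with the
default 0 reproducing plain cross-entropy). Profiles: `paper` (4
layers, 256 hidden/embedding units, accumulation 4) mirrors the
corpus-scale configuration; `desk` (2 layers, 128 units, 400 steps of
batch 20) trains in about a minute on one CPU and memorizes a 200-pair
synthetic corpus to >= 95% exact sequence match, which is the
overfitting sanity check used in the tests. Greedy and beam decoding
are provided; the best hypothesis is returned even if it fails to
parse, feeding the validity metric. Output length is capped at 200
target tokens (observed sequences stay far below this). The trainer
takes an architecture name so other encoder-decoders (e.g. BART-style)
can be registered; only the transformer is implemented.

## Evaluation

* **Validity**: fraction of predictions that parse and reference every
  equation molecule.
* **Normalized Levenshtein similarity**: `1 − d(a,b)/max(|a|,|b|)`,
  computed at character level on the serialized text by default (a
  token-level variant is provided); threshold accuracies at 100/90/75/50%
  are monotone in the threshold by construction and asserted as such.
* **BLEU**: corpus-level, 4-gram, brevity penalty, no smoothing, over
  whitespace tokens.
* **Random baselines**: uniform draws from all training sequences, or
  from training reactions with the query's precursor and product counts
  ("compatible pattern"). Compatible-pattern draws are structurally
  guaranteed 100% valid on pipeline-produced data, because every
  retained sequence references exactly the positions its own equation
  provides — this is the quantity `scripts/acceptance.py` recomputes.
* **Difference taxonomy**: a deterministic cascade — equality; equality
  as multisets (ordering); identical type sequences (property
  differences, singled out for Stir/Add/Reflux); a minimal edit script
  over action types (leftmost-minimal backtrace: diagonal, then
  deletion, then insertion) with exactly one substitution (swap
  categories, named pairs Stir/Reflux, Stir/Microwave, Stir/Wait,
  Add/MakeSolution checked first) or exactly one insertion/deletion
  (action without counterpart, by type), each split by whether all
  aligned actions match exactly; two or more pure deletions/insertions
  (multiple actions only in ground truth/prediction); else remaining.
  The taxonomy gives the category names; the edit-script algorithm and
  its tie-breaking are this package's choices.
* **Length distributions**: histograms of predicted action counts per
  model and per accuracy stratum; unparseable predictions are counted
  separately.

## Synthetic data

The generator emulates raw extracted patent records so that every
stage is testable without proprietary data. Four reaction templates
(carbodiimide-mediated amide condensation, reductive amination,
Williamson etherification, Schotten-Baumann acylation) span precursor
counts 2-5 and carry canonical recipes of 8-10 actions covering the
add/stir/filter/extract/wash/dry/concentrate/purify/yield grammar.
Substituent slots (twelve para/meta aryl substituents, chain lengths,
base choice) give each template hundreds to thousands of distinct
equations. Reversible noise: quantity mentions on Add actions (rate
0.3), name corruptions inside the normalizer's equivalence class (case
changes avoiding dotted i, l/1 and o/0 swaps, dash variants, inserted
spaces; rate 0.3), varied condition spellings whose values stay inside
the recipe's interval, NoAction insertions (rate 0.1), and sometimes
implicit Filter phases that postprocessing must re-infer. Planted
defects mirror the rejection taxonomy at configurable per-category
rates; duplicates reuse an earlier clean equation with a divergent
condition token. Ground truth records the clean pair and the defect
label per record, so tests can assert exact recovery (clean records
survive byte-identically) and exact rejection counts. When a template's
substituent space is exhausted, further draws reuse an earlier clean
equation and are labelled duplicates, keeping counts exactly
predictable at any corpus size.

What the generator does not emulate: real name/structure mismatches in
patent data, extraction noise outside the normalizer's equivalence
class, chemistry beyond the four template families, and free-text
paragraphs (upstream of this tool). Passing tests therefore demonstrate
the correctness of the machinery — standardization, token substitution,
retrieval, training, metrics — not chemical generalization to real
patent corpora.

## Problem sizes and numerical choices

Test suites use 400-record corpora for pipeline/predictor fixtures,
10^4 records for rejection-count recovery, a 200-pair corpus for the
transformer overfitting check, and 10^4 random pairs for the
Levenshtein oracle; the acceptance script uses 2,000 records. These
sizes make the full suite run in a few minutes on one CPU while keeping
every statistical check well-powered. All randomness is seeded; the
pipeline, both predictors, and the generator are deterministic given
(input order, seed). Similarity ties, modal-map ties, nearest-neighbor
ties, and edit-script ambiguities all have documented deterministic
tie-breaks.

## Known limitations

* The action-property schema is the observable subset of the published
  examples; additional extraction action types (Sonicate, Triturate,
  Degas, PhaseSeparation, Partition) are accepted as property-free so
  real data does not crash the pipeline.
* Compound names containing grammar keywords ("with", "for", ...) or
  runs of spaces would not round-trip through the flat text form; the
  pipeline never produces such names.
* The structural fingerprint is a fixed descriptor, not a learned one;
  retrieval quality on diverse real corpora will trail learned reaction
  fingerprints, which is why the vectorizer is pluggable.
* Desk-scale transformer training demonstrates memorization capacity
  and mechanical correctness, not generalization at corpus scale.
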