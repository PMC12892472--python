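# Methods

`extracteval` evaluates an automated extraction of structured study
attributes from research articles against a human-reviewer baseline.  It was
built around the comparison design used for coastal-wetland restoration
literature: 11 attributes per article (study site, latitude/longitude,
ecosystem type, restoration actions, restoration start/end date, sampling
and monitoring methods, monitoring start/end date, focal species, response
variables), each cell holding free-text values or the explicit sentinel
"none reported".

## Data model

A dataset is a complete article × attribute grid for one source (`manual`
or `automated`).  The CSV carrier is long format (one value per row,
columns `article_id, attribute, value[, ontology_source]`); rows for the
same cell merge, the sentinel is case-insensitive, and missing cells are
completed as none-reported records.  Raw text is preserved byte-for-byte
(surrounding whitespace aside): every transformation belongs to the
normalization stage, so reading and re-writing a dataset round-trips.

## Normalization

Term values pass through a fixed pipeline:

1. **Synonym substitution** at phrase level, longest pattern first,
   case-insensitive, each pattern applied once.  The default dictionary has
   exactly three entries — saline→salt, sea grass→seagrass,
   salt marsh→saltmarsh — the compound/variant cases that otherwise block
   obvious matches in this vocabulary.  Substitution precedes tokenization
   because two of the patterns are multi-word.
2. **Tokenization**: lowercase, split on runs of non-alphanumeric
   characters.
3. **Stopword removal** using a standard English stopword list shipped with
   the package (overridable by a one-word-per-line file).
4. **Length filter**: tokens shorter than 3 characters are dropped.  The
   filter runs *before* stemming so no sub-minimum stems are introduced;
   the order is configurable in principle but fixed here for determinism.
5. **Stemming** with the Snowball English (Porter2) algorithm, implemented
   in-package (`_porter2.py`), applied only to attributes flagged as
   stemmed: ecosystem type, restoration actions, sampling and monitoring
   methods, response variables.  Study sites and focal species are left
   unstemmed to keep place names and Latin binomials distinct.

Numerals are ordinary tokens subject to the same length filter.  A known
limitation: Snowball stemming is not idempotent (invasive → invas → inva),
so normalization is defined as applied exactly once per raw value and is
never re-applied to its own output; the non-stemming part of the pipeline
is idempotent and tested as such.  No lemmatization, spell correction or
semantic similarity is attempted — two synonymous terms with dissimilar
character structure (grassland / prairie) will not match.

## Fuzzy multiset matching

Each cell comparison is token-instance-level.  Similarity is Jaro-Winkler
(in-package implementation, standard parameters: prefix weight 0.1, boost
over at most 4 characters, no boost threshold), with distance
= 1 − similarity.  A token pair is *eligible* when distance ≤ 0.15 if the
tokens share their first three characters, else ≤ 0.05.  A 1e-12 epsilon
guards the comparisons against float representation error at the
boundaries (a pair whose similarity is exactly 0.95 in real arithmetic
must remain eligible).

Matching is greedy and deterministic: exact string matches first, then
same-prefix eligible pairs by descending similarity, then different-prefix
eligible pairs, ties broken on the unordered token pair.  The symmetric
tie-break makes the matcher provably swap-symmetric (exchanging the inputs
exchanges FP and FN and preserves TP), which the suite fuzz-tests.  Each
matched instance is a TP; the number of matches consuming a manual token is
capped at its multiplicity, so automated duplicates above the cap are FP;
leftover automated instances are FP, leftover manual instances FN; a cell
where both sources reported nothing is one TN.  When only one side is
empty, all tokens of the populated side are FP (automated) or FN (manual).
Greedy assignment is not globally optimal in pathological eligibility
graphs; the suite bounds it against a brute-force maximum-cardinality
oracle on small multisets and proves equality when the eligibility graph
is a union of cliques (which exact-only matching always is).

## Coordinates and dates

Coordinates are parsed to signed decimal degrees from decimal,
degrees-minutes, and degrees-minutes-seconds forms, with hemisphere
letters on either side (S/W negative) and symbol or space separators;
unparseable values are recorded as typed parse failures and contribute no
extracted value.  Pairs match one-to-one when both |Δlat| and |Δlon| are
within ±0.01° (a per-axis Chebyshev criterion, not great-circle distance),
closest first.  Dates match at year resolution: every four-digit substring
in [1500, 2100] bounded by non-digits counts as a year, a range such as
"2009–2012" contributes both endpoints, and TP per year is the minimum of
the two multiplicities.  The year window excludes page numbers and most
measurement values while covering any plausible restoration date.

## Metrics

Per attribute: precision TP/(TP+FP), recall TP/(TP+FN), accuracy
(TP+TN)/(TP+TN+FP+FN), F1 = harmonic mean of precision and recall.  Any
zero denominator yields an explicit undefined marker, never 0 or a crash.
Macro averaging is the unweighted arithmetic mean over attributes — for F1
as well (the mean of per-attribute F1s, not the harmonic mean of macro-P
and macro-R; the two conventions differ by nearly two points on the
case-study table and only the former reproduces it).  Micro averaging
pools the confusion tables element-wise and computes metrics once.
Percentages are displayed with half-up rounding to one decimal; all
internal arithmetic is full precision.

The sampling margin of error for drawing n articles from a population of N
is `z·sqrt(p(1−p)) / sqrt((N−1)·n/(N−n))`, with the conservative p = 0.5
and z = 1.96 by default; 80 of 496 gives 0.1004, reported as ±10%.

## Agreement scoring

Human reviewers score each cell 2 (full agreement), 1 (partial: at least
one piece of information agrees) or 0 (disagreement).  Attribute agreement
is 100·(2·full + partial)/(2·cells), i.e. the percentage of the maximum
possible score (160 for an 80-article sample).  Human-assigned scores are
data, ingested by CSV; the package can *suggest* scores mechanically from
match outcomes (2 iff everything matched or both sides empty, 1 iff
anything matched, 0 otherwise), but the suggestion is stricter than a
human rating — reviewers allow semantic leeway (tidal reinstatement vs.
tidal flow restoration) that string matching cannot — and suggested scores
never overwrite human ones.  Replicate agreement between two runs of the
same extractor is the mean per-cell fraction of values agreeing, under
exact equality or fuzzy eligibility.

## Synthetic corpus generator

The generator emulates the study conditions so the whole pipeline is
testable offline.  Entry counts per cell are 1 + Poisson(rate − 1) with
per-attribute rates defaulting to the observed manual extraction rates
(study site 1.7 … response variables 5.3 entries per article).  Vocabulary
comes from a built-in ~200-term coastal-wetland lexicon (place names,
Latin binomials, ecosystem/action/method/response terms).  The automated
side is derived value by value through a single perturbation channel per
value: exact copy, near-miss typo, synonym swap, compound split, or
omission; per cell, a spurious addition, duplicate inflation, or a jointly
empty ("none reported") pair may occur; coordinates jitter within or
beyond tolerance; years drift.  Default channel probabilities (omission
0.30, spurious 0.25, typo 0.08, duplicate 0.08, split 0.06, synonym 0.04,
jointly-empty 0.10, jitter 0.20/0.10, drift 0.15) were chosen once to
produce the false-negative-heavy, sizeably false-positive regime observed
when LLM extraction is scored against a careful human baseline.

Ground-truth confusion counts are exact by construction, which requires
three guarantees: distinct base terms in a cell are rejection-sampled to
be pairwise ineligible after normalization; typos are validated on the
whole term (the normalized multiset must be unchanged except one token
replaced by an eligible, non-colliding variant — a typo inside a synonym
phrase such as "salt marsh" would otherwise restructure the tokens) and
are resampled or degraded to exact copies when no valid typo exists; and
synonym swaps and compound splits must be invisible after normalization,
falling back to exact copies when splitting would sever a synonym phrase.
Coordinates in one cell are separated by ≥ 0.1° so jitter can never reach
a foreign pair.  The central property — pipeline-computed confusion tables
equal the generator's bookkeeping exactly, for arbitrary rate settings —
is exercised over randomized specifications in the test suite and the
acceptance script.

What the generator does *not* emulate: real LLM behaviour (hallucinated
prose, ontology-grounding artefacts, semantically equivalent rephrasings),
document structure, or correlated errors across attributes.  Passing the
recovery property shows the matching and tallying arithmetic is exact, not
that the thresholds are well calibrated for any particular extractor.

## Problem sizes and numerical choices

The suite runs the recovery property on corpora from 5 to 80 articles plus
one 500-article Monte-Carlo check of closed-form metric recovery
(omission-only corpus: precision 1, recall 1 − rate ± 0.02); these sizes
make the full suite complete in well under a minute while exercising every
channel.  All randomness flows through a single integer seed
(`numpy.random.default_rng`); identical spec and seed reproduce the corpus
byte for byte.  Display rounding is decimal half-up (78.75 → 78.8), chosen
to reproduce published tables that Python's banker's rounding would not.
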