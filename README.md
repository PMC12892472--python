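# extracteval

Evaluate automated extraction of structured study attributes from research
literature against a human-reviewer baseline.

Evidence syntheses (systematic maps and reviews) extract the same fields
from every included article — where a study happened, what ecosystem it
concerned, what was done, what was measured.  LLM-based extractors can fill
those tables quickly, but their output has to be scored against what a
careful human reviewer extracts.  `extracteval` implements that scoring for
datasets shaped like the coastal-wetland restoration comparison it was
built around: 11 attributes per article (terms, geographic coordinates,
dates), free-text values, and an explicit "none reported" sentinel for
empty cells.

## What it computes

* **Attribute-aware normalization** — phrase-level synonym substitution
  (saline→salt, sea grass→seagrass, salt marsh→saltmarsh), tokenization,
  English stopword removal, a ≥3-character token filter, and Snowball
  English stemming for concept-like attributes (place names and Latin
  binomials stay unstemmed).
* **Capped fuzzy multiset matching** — token instances pair when their
  Jaro-Winkler distance is ≤ 0.15 with a shared three-character prefix, or
  ≤ 0.05 otherwise; exact matches first, then by descending similarity.
  TP matches per term are capped at the term's multiplicity in the manual
  extraction; surplus automated duplicates are FP, unmatched manual tokens
  FN, and a cell empty on both sides is one TN.
* **Coordinate and date matching** — coordinates parsed from decimal or
  DMS forms to decimal degrees and matched within ±0.01° per axis; dates
  matched on the year.
* **Metrics** — per attribute and pooled: precision TP/(TP+FP), recall
  TP/(TP+FN), accuracy (TP+TN)/(TP+TN+FP+FN), F1 (harmonic mean), with
  macro (unweighted mean, including of F1) and micro (pooled counts)
  averages, and the finite-population sampling margin of error
  z·√(p(1−p))/√((N−1)n/(N−n)).
* **Agreement scoring** — weighted 2/1/0 reviewer agreement per attribute
  as a percentage of the maximum score, mechanical score suggestion from
  match outcomes, and replicate-run agreement (exact or fuzzy).
* **Synthetic corpora** — a seeded generator of paired manual/automated
  datasets with exact, by-construction ground-truth confusion counts, so
  every stage is testable offline.

## Worked example

Generate an 8-article synthetic corpus and evaluate it:

```bash
$ extracteval simulate --out demo --n-articles 8 --seed 1
wrote corpus for 8 articles to demo
ground-truth recovery check: PASS

$ extracteval evaluate --manual demo/manual.csv --automated demo/automated.csv --out demo/eval
Extraction evaluation (automated vs. manual baseline)
  cells compared : 88
  pooled counts  : TP=192 FP=41 FN=91 TN=6
  coordinate parse failures: 0

                      attribute  manual_items    TP   FP   FN  TN  precision  recall  accuracy   f1
                     study site          23.0  17.0  4.0  6.0 0.0       81.0    73.9      63.0 77.3
             latitude/longitude          11.0   7.0  3.0  4.0 0.0       70.0    63.6      50.0 66.7
                 ecosystem type          24.0  17.0  1.0  7.0 0.0       94.4    70.8      68.0 81.0
...
                  Macro-average           NaN   NaN  NaN  NaN NaN       75.9    63.4      55.5 68.8
                  Micro-average           NaN   NaN  NaN  NaN NaN       82.4    67.8      60.0 74.4
```

The "recovery check" asserts that the confusion counts the pipeline
computes equal the generator's recorded ground truth exactly — the
generator knows, value by value, which perturbations it applied (typos
within the fuzzy threshold, synonym swaps, omissions, spurious additions,
duplicate inflation, coordinate jitter, year drift).  The table is the
standard report: one row per attribute with its confusion counts and the
four metrics as percentages, then pooled totals and the macro/micro
averages.  `manual_items` is TP+FN, the number of manually extracted items.

The margin of error for sampling 80 articles from a 496-article pool:

```bash
$ extracteval moe 496 80
MOE = 0.100444 (±10.0%)
```

Each computation is also available directly:

```python
from extracteval import ConfusionTable, compute_metrics

compute_metrics(ConfusionTable(tp=86, fp=18, fn=0, tn=29)).as_percent()
# {'precision': 82.7, 'recall': 100.0, 'accuracy': 86.5, 'f1': 90.5}
```

The package ships the published per-attribute confusion and agreement
tallies of the coastal-wetland restoration case study as example data
(`extracteval/data/example_confusion.csv`, `example_agreement.csv`);
`extracteval metrics --confusion …` and `extracteval agreement --counts …`
rebuild the full published metric and agreement tables from those raw
counts.

## Layout

```
src/extracteval/
  records_io.py     data model, CSV ingestion, attribute registry, tallies
  normalization.py  synonym/tokenize/stopword/length/stem pipeline
  term_matching.py  Jaro-Winkler eligibility and capped greedy matching
  value_matching.py coordinate parsing/matching, year matching
  metrics.py        confusion tables, metrics, macro/micro, margin of error
  agreement.py      2/1/0 scoring, suggestion, replicate agreement
  synthetic.py      seeded corpus generator with exact ground truth
  evaluate.py       cell-by-cell evaluation and reporting
  cli.py            `extracteval` command-line interface
docs/methods.md     full description of the model and its choices
```
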