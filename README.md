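# cardext

Extraction of presenting symptoms and discharge medications from free-text
hospital discharge summaries, plus the gender-disparity statistics built on
the extracted indicators and a synthetic corpus generator for testing the
whole pipeline without patient data.

The package has six parts:

- **lexicon** — the symptom lexicon (18 canonical concepts, including the
  cultural term *ghabrahat*) and the medication dictionary (9 drug classes),
  both user-replaceable via JSON/CSV files.
- **docparse** — section segmentation, presenting-complaint passage isolation
  (heading match, then trigger-phrase fallback), medication-table detection.
- **symptoms** — fuzzy phrase matching with a character-level normalized
  Levenshtein similarity (`100 * (1 - LEV/maxlen)`), an inclusive 80-point
  threshold, token-window sliding per synonym, and preceding-window
  sentence-bounded negation detection.
- **meds** — medication row parsing (dosage-form/dose/route stripping),
  base-term extraction, exact + strict-fuzzy (threshold 90) drug-class
  lookup, and an unknown-term queue for manual labeling.
- **stats** — cohort assembly with flow accounting, 2x2 contingency tables,
  univariate odds ratios with Woolf CIs (zero-cell rows are omitted, not
  corrected), Pearson chi-square, Mann-Whitney, and covariate-adjusted odds
  ratios from an explicit Newton-type logistic MLE with Wald intervals.
- **synth** — a deterministic generator of discharge-summary corpora with
  matched ground truth: per-gender symptom/medication prevalences, document
  layout variants, single-edit typo injection, and negation phrasings drawn
  from the extractor's own cue vocabulary.

## Command line

```sh
# generate a synthetic corpus with ground truth
cardext simulate --n 1000 --seed 7 --out corpus.jsonl --truth truth.jsonl

# run the extraction models
cardext extract-symptoms --corpus corpus.jsonl --threshold 80 --out symptoms.csv
cardext extract-meds --corpus corpus.jsonl --out meds.csv --unknowns unknowns.csv

# score predictions against ground truth
cardext evaluate --truth truth.jsonl --pred symptoms.csv

# statistics tables (frequencies, univariate + adjusted odds ratios)
cardext stats --corpus corpus.jsonl --out results/

# or the whole pipeline from one YAML config, with a run manifest
cardext run --config run.yaml --out results/
```

A `run.yaml` contains a `simulate:` block (generator settings) or a
`corpus:` path, plus an optional `extract:` block (`threshold`,
`negation_window`, `fuzzy_threshold`, `lexicon`, `dictionary`).

## File formats

- Corpus: JSON-lines, one object per summary with `doc_id`, `text`,
  `gender` (`woman`/`man`), `age_years`, `admission_year`, `diabetes`, `pci`.
- Symptom lexicon: JSON array of `{"canonical": str, "synonyms": [str]}`.
- Medication dictionary: CSV with header `name,class`.
- Outputs: doc-by-indicator binary CSV matrices, statistics tables as CSV,
  flow counts and run manifest as JSON.
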