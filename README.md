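# headache-nlp

Text mining of self-reported headache narratives: a tested, reusable
pipeline for analysing free-text descriptions written by patients with
**migraine** or **cluster headache**, and for classifying a narrative into
its diagnosis group.

Clinicians diagnose primary headache disorders almost entirely from the
patient's own linguistic description of their attacks.  This package
provides the quantitative counterpart for researchers working with such
corpora:

- **Corpus statistics** — per-group demographics and token/type/sentence
  summaries (median, Q1–Q3).
- **Keyness** — signed 2×2 chi-square per word type between the two
  diagnosis groups, with significance tiers `*` (p < 10⁻²), `**`
  (p < 10⁻⁵), `***` (p < 10⁻⁸):

  χ² = N(|ad − bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d))

  for word counts a, b in target/reference and remaining tokens c, d.
- **Themes** — per-text proportions of seven sentence-level themes (attack
  description, burden of disease, comorbidities, technical investigations,
  triggers, treatment, medical history) from stand-off annotations, and
  extraction of the attack-description subcorpus.
- **Sentiment** — an ordered lexicon cascade with first-match-wins lookup;
  a document's score is the sum of matched token valences (normalised to
  [−1, +1]), its polarity the sign of the sum.
- **Classification** — naive Bayes, linear SVM and logistic regression on
  word/character n-grams (n = 1–3) and patient metadata, evaluated with
  nested stratified 5-fold cross-validation (inner macro-F1 grid search
  over C ∈ {0.1, 1, 10, 100}) and leave-one-out CV, with a built-in
  leakage audit trail.
- **Synthetic data** — a seeded generator producing study-shaped corpora
  (81/40 records, realistic lengths, theme mix, ~90% negative sentiment,
  class-exclusive keywords) with recountable ground truth, so every stage
  is testable without patient data.

## Worked example

```python
import headache_nlp as h
from headache_nlp.classification import ClassifierSpec, CVPlan, FeatureSpec

corpus, annotations, truth = h.generate_corpus(h.GeneratorConfig(seed=17))
docs = h.tokenize_corpus(corpus)
attacks = h.extract_theme_subcorpus(corpus, annotations, docs, "attack_description")
ml_docs = h.preprocess_corpus(attacks, blocklist=h.default_blocklist(),
                              stopwords=h.default_stopwords())
report = h.nested_cv(attacks, ml_docs, FeatureSpec(),
                     ClassifierSpec(algorithm="logistic_regression"),
                     CVPlan(seed=17))
print(report.aggregate["accuracy"], report.aggregate["macro_f1"])
```

prints

```
0.9110671936758894 0.8946719193549004
```

the fold-averaged accuracy and macro-F1 of logistic regression with n-gram
features on the 112-record attack-description subcorpus (74 migraine / 38
cluster headache): with the generator's default signal strength the
classifier recovers the injected class vocabulary almost perfectly.  The
keyness stage ranks exactly those injected words on top (`terug`, `tanden`,
`linker`, `oog`, `pijn` toward cluster headache; `vaak`, `misselijkheid`,
`geluid`, `stress`, `hoofdpijn` toward migraine, all tier `***`), and the
sentiment stage reports ~91% of documents as negative, matching the
configured 90% injection rate.

The `examples/` directory has one short script per capability
(`01_generate_corpus.py` … `05_classification.py`); each builds a small
input, runs one stage and prints what the numbers mean.

## Command line

The same stages are available as subcommands for file-based workflows:

```bash
headache-nlp synth --seed 17 --outdir data/
headache-nlp preprocess --in data/corpus.jsonl --out data/tokens.jsonl
headache-nlp keyness --corpus data/corpus.jsonl --tokens data/tokens.jsonl \
    --target cluster_headache --reference migraine --out keyness.csv
headache-nlp run-all --seed 17 --outdir run/   # full pipeline + manifest
```

`run-all` writes a manifest with the seed and SHA-256 of every artifact;
re-running with the same seed reproduces identical hashes.

Formats: corpora as JSONL (`record_id`, `text`, `diagnosis`, `age`, `sex`),
CSV for interchange; lexicons as headerless `word<TAB>valence` TSV; theme
annotations as stand-off JSON keyed by sentence index; word lists as plain
text with `#` comments.

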