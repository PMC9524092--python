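# Methods

`headache_nlp` re-implements, as a tested and reusable pipeline, a
text-mining analysis of free-text narratives written by patients with one
of two primary headache disorders — migraine or cluster headache.  The
pipeline covers five analyses: corpus statistics, chi-square keyness,
sentence-level theme proportions, lexicon-cascade sentiment scoring, and
binary diagnosis classification under nested stratified cross-validation.
Because no patient corpus ships with the package, a synthetic-narrative
generator reproduces the statistical structure of such a corpus and
provides ground truth for every stage.

## Pre-processing

Cleaning normalises unicode to NFC, strips control characters and
collapses whitespace runs; a run containing a line break collapses to a
single newline because patient texts often use bare line breaks as
sentence boundaries, and the sentence splitter honours them.  Cleaning is
idempotent.

Sentences end at `.`, `!`, `?` or a newline, with two guards: a period
inside a decimal number (`8.5`) and a period after a configurable
abbreviation list (default: common Dutch abbreviations such as *dr.*,
*bijv.*) do not split.  The tokenizer is rule-based and pluggable: maximal
runs of unicode word characters, with internal hyphens and apostrophes kept
inside the token, lowercased; punctuation is discarded from the word-token
stream.  A *token* is one occurrence; a *type* is the equivalence class of
identical character sequences ("time after time": 3 tokens, 2 types).

Two word-list filters follow for the machine-learning corpus: a
*blocklist* removing diagnosis labels and label-revealing terms (drug
names, "aura", ...) so the classifier cannot read the answer off the page,
and a Dutch *stop-word* list.  The sentiment stage keeps stop words —
source lexicons may score negators and intensifiers — but still applies
the blocklist.  Filtering preserves token order and drops sentences left
empty; blocklist and stop-word removal commute.

Open choices made here: lowercasing at tokenization (keyness and lexicon
lookup need case folding), and counting Table-style corpus statistics on
the unfiltered token stream.

## Corpus statistics

Age and sex are summarised as mean (SD) and count (percent female); token,
type and sentence counts per text as median (Q1–Q3), appropriate for their
skewed distributions.  Quartiles use linear interpolation between order
statistics (the "type 7" rule) — the convention must be fixed for
deterministic, oracle-checkable output.

## Keyness

For each word type, a 2×2 table contrasts its count in the target and
reference subcorpora against all other tokens, scored with the closed-form
2×2 chi-square

    chi2 = N (|ad − bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d))

with the Yates continuity term (clipped at zero) applied by default — the
conservative choice for sparse word counts — and removable by flag (the
uncorrected statistic is exactly 0 on proportionally identical
distributions).  The statistic is unsigned; the direction (which group
over-uses the word) is carried separately, so the "absolute chi-square" of
keyword plots is the statistic itself.  P-values come from the chi-square
distribution with 1 df; significance tiers are `*` p < 1e-2, `**` p < 1e-5,
`***` p < 1e-8.  Words with combined count below `min_count` (default 5)
are dropped because single-occurrence keys are unstable; ties in the
ranking break alphabetically.  Keyness runs on the blocklist- and
stop-word-filtered stream, since keywords of interest are content words.

## Themes

Narratives carry stand-off sentence-level annotations from a closed set of
seven themes (attack description, burden of disease, comorbidities,
technical investigations, triggers, treatment, medical history).  A theme's
weight in a text is the fraction of the text's word tokens lying in
sentences that carry the theme; unannotated sentences count only in the
denominator.  Sentences may carry several themes; each proportion is
computed independently, so proportions can sum above 1 under overlap.
Proportions are computed on raw (unfiltered) tokens.  The
attack-description subcorpus — the input to classification — concatenates
each record's attack-description sentences in order and drops records
without any.

## Sentiment

An ordered cascade of sentiment lexicons is consulted with first-match-wins
semantics (modelled on a Pattern → in-house → Duoman → NRC ordering; any
TSV cascade is accepted — real Dutch lexicons are not bundled for licensing
reasons, and generated toy fixtures stand in, labelled as synthetic).  Each
lexicon's native scale is harmonised at load by dividing by its maximum
absolute valence, mapping into [−1, +1] while preserving sign.  A
document's score is the plain sum of matched token valences, each
occurrence counted; there is no negation or intensifier arithmetic — the
known failure mode (positive words inside negative contexts) is accepted
and documented rather than patched.  Polarity is a strict two-way split:
positive iff score > 0, otherwise negative; the zero/no-match boundary maps
to the majority clinical polarity (negative) and is flag-configurable.

## Classification

Feature families:

- **word n-grams**, n = 1–3, within sentence boundaries;
- **character n-grams**, n = 1–3, inside `#`-padded tokens, so n-grams
  never span the gap a removed stop word leaves behind;
- **metadata**: age and a sex indicator.

Weighting is raw counts by default (binary and tf-idf by flag).  The
vocabulary, idf weights and age scaling are always fitted on training
portions only; unseen n-grams in held-out documents are ignored.  Age is
standardised with training-fold mean/SD for SVM and logistic regression;
multinomial naive Bayes cannot take negative features, so for it age is
min–max scaled to [0, 1] on the training fold (clipped at test time).

Classifiers: multinomial naive Bayes, linear-kernel SVM and logistic
regression.  "Balanced class weighting" is given one concrete meaning per
algorithm: uniform class priors for NB, inverse-frequency class weights for
SVM/LR.  The hyperparameter grid is {0.1, 1, 10, 100} — a log grid over
the regularisation range, with the gridded NB parameter being the additive
smoothing strength.  SVM optimisation is capped at 2000 dual iterations:
ample on separable text data, and an early stop rather than an
unattainable-optimum chase on noise.

Evaluation is nested stratified 5-fold cross-validation: within each outer
training portion, an inner stratified 5-fold grid search maximises
macro-averaged F1 (equal class weight, deliberately favouring the minority
cluster-headache class); ties break toward the first-listed value.  The
winner refits on the full outer training portion and predicts the held-out
fold.  Reported headline metrics are fold-averages; pooled-prediction
metrics are also returned.  Leave-one-out CV is the N-round special case
(no outer stratification is possible with singleton test sets; the inner
grid search remains stratified) with metrics pooled over the N single
predictions.  Reports carry an audit trail — outer/inner membership lists,
a SHA-256 fingerprint of each fitted vocabulary and the metadata scaling
statistics — so the no-leakage guarantee is checkable, and are bitwise
reproducible given (corpus, specs, seed).

## The synthetic-data generator

The generator emits token streams, not fluent Dutch: every consumer stage
is token-based, so linguistic realism buys nothing.  Its defaults are the
study conditions:

| dial | default | rationale |
| --- | --- | --- |
| records per class | 81 migraine / 40 cluster headache | study cohort |
| records without attack description | 7 / 2 | yields the 112-record (74/38) ML subcorpus |
| token count per text | log-normal, median 474 / 508, σ 0.88 / 1.03 | medians and IQRs of the reported text lengths |
| tokens per sentence | Poisson, mean 20 (min 3) | gives ~23 sentences per median text |
| theme mix per sentence | attack 0.30, treatment 0.17, history 0.12, burden 0.12, triggers 0.04, comorbidities 0, technical 0, rest unannotated | reported theme-proportion medians |
| class keywords | *oog, pijn, terug, linker, tanden* vs *hoofdpijn, stress, misselijkheid, geluid, vaak* | the clinically expected distinctive vocabulary, so keyness output is human-checkable |
| keyword rate | 0.04 per token | unreported; chosen so the ML task is learnable but not trivial at n = 112 |
| label-mention rate | 0.01 | exercises blocklist filtering end-to-end |
| stop-word rate | 0.25 | realistic function-word share |
| sentiment-token rate | 0.10 | unreported; gives every text a scoreable sentiment load |
| P(document net-negative) | 0.90 | the reported 86–96% negative band |
| age | N(43.1, 12) / N(48.9, 14.2), ≥ 18 | reported group demographics |
| P(female) | 0.80 / 0.20 | reported group demographics |

Background tokens are pronounceable CV-syllable words drawn Zipf-like from
a shared 400-type vocabulary; sentiment words come from four generated toy
lexicons (sizes 40/20/30/50, different native scales, eight words shared
between lexicons 1 and 3 with opposite signs to exercise first-match
semantics).  The word pools — background, keywords, stop words, sentiment
words, label mentions — are disjoint by construction, which is what makes
ground truth exactly recountable from the emitted text.  Each document's
net valence is forced to its drawn polarity by replacing tokens until the
sign matches, so the corpus-level negative share is an exact binomial draw
of the configured probability.  All randomness flows through one seeded
generator; identical configs give byte-identical output, which
`verify_ground_truth` re-derives from the text alone.

What the generator does **not** emulate: real narratives share vocabulary
across classes (here class keywords are exclusive), have grammar, topic
drift, spelling noise, and annotation ambiguity.  Passing tests therefore
demonstrate that the machinery is correct and leak-free and that known
signal is recovered — not that real-corpus scores are reproduced, which
would require the original (non-deposited) texts.

## Null calibration

On zero-signal corpora (keyword and label-mention injection off, one
shared length model) the nested-CV estimate must show no optimistic bias.
Note that with balanced class weighting the null expectation of accuracy
is chance level (~0.5), *below* the majority rate (0.66): balanced weights
make null predictions approximately symmetric coin flips.  The calibration
check is therefore one-sided — pooled null accuracy over 20 seeds must not
exceed the binomial 99% upper bound of the majority rate, and macro-F1
stays near chance — rather than a two-sided band around the majority rate,
which no balanced-weight classifier could satisfy.

## Numerical and degenerate-input choices

- Chi-square correction term clipped at zero (no spurious positives from
  over-correction of near-null tables).
- Zero-division in precision/recall scores 0 with a logged warning.
- A document with no lexicon match scores 0 → negative polarity, logged.
- Empty sentences after filtering are dropped; zero-token documents are
  rejected by the stages that cannot handle them (theme proportions,
  summaries).
- Readers reject malformed input (naming the line) rather than repairing.

## Problem sizes in tests and the acceptance script

The test suite runs the full pipeline at the study scale (121 records; the
74/38 attack subcorpus) for signal recovery and leakage audits, 20
study-scale corpora for null calibration, and 300 records per class for
distributional checks of the generator; the acceptance script runs one
study-scale corpus end-to-end including nested CV for all three
classifiers and LOOCV for logistic regression.  These sizes were chosen to
match the study conditions while keeping a full run in the minutes range
on one CPU.

## Known limitations

- Synthetic class-exclusive keywords make the classification task easier
  than the real clinical task; reported synthetic scores are not estimates
  of real-corpus performance.
- The tokenizer is language-agnostic; it does not handle Dutch clitics or
  compound splitting.
- No neutral sentiment class, no negation handling, no aspect-based
  analysis.
- Binary classification only; no multi-class support.
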