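# Methods

`chfpheno` implements an EHR phenotyping pipeline for congestive heart
failure (CHF): given a patient's clinical notes, dated diagnosis-code events,
and dated medication events, it produces a per-note probability that the note
affirms a CHF diagnosis. This note records the statistical model, the design
choices that were genuinely open, the synthetic data the package is validated
on, and the limits of what that validation shows.

## Screening groups and cohort assembly

Patients are screened into four groups by two binary flags: ICD± (any
diagnosis code whose dot-stripped form starts with stem `428` (ICD-9 heart
failure) or `I50` (ICD-10 heart failure)) and MED± (any medication event
equal to one of nine generic names: lisinopril, furosemide, bumetanide,
propranolol, amlodipine, hydrochlorothiazide, omeprazole, isosorbide
mononitrate, enalapril). Group membership uses the patient's entire event
history, since screening precedes the choice of any particular note. Code
normalization strips dots and whitespace and uppercases before prefix
matching; medication matching is exact on the whole value
(case/whitespace-insensitive), with a separate dose/route-stripping
normalizer (`normalize_medication`) that the I/O loaders apply to raw
prescription strings such as `"FUROSEMIDE 40MG PO"`.

The modelling sample is drawn per group, restricted to notes containing at
least one screening keyword (default `heart`, `chf`, `congestive`;
configurable — the keyword filter is a recall device, not part of the
model). Sampling is without replacement; a quota exceeding the eligible pool
returns the whole pool with a warning.

## Keyword lexicon

Text features are occurrence counts of lexicon phrases. The lexicon has
three strata:

- **curated** — a clinician-style seed list (`chf`, `congestive heart
  failure`, `heart failure`, `history of chf`, `chf exacerbation`,
  `with chf`, `dx chf`, `ascites`);
- **data-driven** — all 1/2/3-grams in the corpus, counted per note on the
  normalized token stream (overlapping, never crossing a sentence
  boundary), compared between proxy-positive and proxy-negative notes with
  a two-sided Mann-Whitney U test. The proxy label is the patient's ICD
  screening status, so discovery never touches manual annotations. Grams
  occurring in fewer than 5 notes are pruned before testing (rank tests on
  near-constant vectors are noise); significance is Benjamini-Hochberg at
  α = 0.05. All three thresholds are configurable: the α level, the
  correction, and the frequency cutoff are implementation choices, since a
  raw 0.05 over millions of n-grams would be vacuous.
- **negation** — for each base phrase and each template in
  `no {p}`, `unlikely {p}`, `{p} father`, `{p} mother`, `[] {p}`, `() {p}`,
  a negated entry is added. A negated mention increments both the base and
  the negated column; the classifier weighs them against each other, which
  is how family-history and checkbox mentions acquire negative weight. In
  the end-to-end pipeline, templates are applied to curated bases only:
  negating every discovered context fragment multiplies the feature space
  roughly sevenfold with strings that never occur, while genuinely negated
  forms are themselves discoverable n-grams.

Mann-Whitney details: U is the pairwise wins-plus-half-ties statistic for
the proxy-positive group. For small tie-free samples (n₊·n₋ ≤ 400) the
exact null distribution is used; otherwise a normal approximation with tie
and continuity correction. Corpus-wide discovery uses a vectorized
columnwise implementation of the same approximation, cross-checked in the
test suite against the scalar path, an exhaustive pairwise oracle, and a
permutation oracle.

A caution observed on synthetic data and expected on real data: raw
occurrence counts are confounded by note length. Any chance correlation
between length and the proxy label makes many content-free grams jointly
"significant". The elastic net downweights these, but the lexicon should be
read as high-recall, not as a curated clinical vocabulary.

## Feature matrix

Each labeled note becomes one row with three column blocks:

- **notes** — counts of each normalized lexicon phrase. Normalization is
  lowercasing, punctuation stripping (preserving `[]` and `()` checkbox
  markers as standalone tokens), a light plural-folding lemmatizer, then a
  Porter stemmer — so lexicon forms look like `histori congest heart
  failur`. Curated phrases are normalized at lexicon load, guaranteeing one
  shared token space. Counts are raw (no tf-idf, no binarization).
- **icd** — per stem (`428`, `I50`), the number of the patient's code
  events dated within the closed interval [note − 18 months, note + 18
  months]. "Month" is calendar arithmetic with month-end clamping
  (Jan 31 + 1 month = Feb 29/28); each dated event row counts once.
- **med** — the same windowed count per screening medication.

Feature extraction is pure, and the full matrix equals the column-wise
concatenation of the three single-modality matrices.

## Classifiers and nested cross-validation

Two model families: logistic regression with an elastic-net penalty
(standardized features, saga solver) and a random forest. Hyperparameters —
penalty strength C log-uniform on 10⁻⁴…10⁴ and l1_ratio uniform on 0…1 for
the LR; min_samples_leaf 1…50, n_estimators 50…500, max_depth 2…32,
ccp_alpha log-uniform 10⁻⁶…10⁻¹ for the forest — are tuned inside a nested
5×5 cross-validation: for each outer fold, candidates are scored by mean
inner-fold AUROC on the outer-training set only, the best is refit on the
outer-training set, and evaluated once on the outer test set. The headline
metric is the arithmetic mean of the five outer AUROCs.

The candidate stream is a budgeted random search (default budget 50): the
search backend is a pluggable candidate sampler, and the bundled sampler
draws a seeded prefix sequence so that enlarging the budget can only add
candidates (best inner AUROC is monotone in budget, which the tests
assert). Folds are grouped by patient and stratified by label by default —
notes from one patient are near-duplicates and would otherwise leak across
folds; note-level splitting remains available.

A Youden-index cutoff (maximizing sensitivity + specificity − 1, ties
toward the higher threshold, predictions positive at score ≥ threshold) is
derived per outer fold; the deployed pipeline refits with the median
hyperparameters across folds on all training data and uses the mean of the
per-fold cutoffs as its decision threshold.

Feature importance is the signed LR coefficient (on the standardized
scale) ranked by magnitude, or the forest's Gini importances, which are
normalized to sum to one. Class imbalance is not reweighted. An optional
|coefficient| pruning threshold for deployment exists but is off by
default, as no principled value presents itself.

Numerical choices: saga with tol 10⁻³ and max_iter 2000 — on wide count
matrices tighter tolerances cost minutes per fit without changing fold
AUROCs at the reported precision; AUROC is the tie-aware rank statistic
(identical to U/(n₊n₋), asserted against the keywords module); AUPRC is
step-interpolated average precision.

## Embedding path

For transformer-style encoders, a note is one fixed-width vector: the
elementwise mean of segment encodings. `whole_note` chunking packs
sentences greedily into ≤512-token segments with a one-sentence overlap
(the overlap is included only when the pair fits; oversized sentences are
hard-split with a warning). `keyword_window` takes 250 tokens either side
of each anchor occurrence (`chf`, `congestive heart failure`, matched on
the lowercased raw token stream — anchors are not stemmed), clipped to the
note; with no anchor the vector is all zeros. The bundled backend is a
deterministic md5-hashing bag-of-tokens stub with a fixed dimension —
bit-reproducible, dependency-free, and sufficient to pin down the chunking
and averaging contracts; real pretrained encoders plug in by satisfying the
same `EncoderBackend` protocol. Token accounting follows the attached
backend's tokenizer.

## External validation and population error

Cross-site validation refits everything — lexicon and model — on the
training site only and scores the held-out site; overlapping patient ids
raise. Confidence intervals are percentile bootstrap (default 10,000
resamples at 95%), resampling notes, with a patient-level cluster bootstrap
as an option; resamples with a single class are redrawn. Percentile rather
than BCa is the minimal reading of "bootstrap CI"; the method is
configurable.

The modelling sample is enriched by construction, so its error rate is
extrapolated to an unselected population by stratification:

    P(E) = Σ_g Pe_g · p_g

where Pe_g is the misclassification rate measured in the annotated sample
for group g and p_g the group's positive prevalence in a random sample,
both computed from raw counts rather than pre-rounded rates. The weights
p_g are within-group prevalences and do not sum to one; the estimate is a
faithful implementation of this published form, the report flags the weight
total, and an alternative weighting by group share of the random sample is
available behind a flag without any claim that it is the original method.
On the bundled reference counts both the raw-count path and the
rounded-rate path round to 1.6%.

## The synthetic cohort: what it emulates and what it does not

The generator produces the statistical structure the pipeline assumes: a
two-site population with group mix (14.0%, 4.1%, 34.2%, 47.7%) and
within-group positive prevalences (10%, 9.8%, 0.88%, 0.21%) — i.e. an
unselected cohort that is ~2% positive; note lengths log-uniform over
1,907–60,870 characters; notes assembled from sentence templates (header,
findings, family history, plan, boilerplate) plus filler to reach the
target length. Positive notes always carry at least one affirmation phrase
(a stated personal history of CHF counts as positive); negative notes may
carry explicit negations ("no CHF", "unlikely CHF"), family-history
mentions ("CHF mother"), templated boilerplate ("tell your doctor if you
have CHF", checkbox lines like "[ ] CHF"), and bare screening keywords —
at rates 10%, 10%, 15% respectively (boilerplate 15%), none of which flip
the label. ICD+ patients receive 428/I50-stem events and MED+ patients
screening-medication events, placed uniformly within ±540 days of the note
date with a 10% fraction deliberately beyond ±18 calendar months so the
window boundary is testable; positives receive extra events, correlating
structured data with the label. One seed sequence per cohort is split
hierarchically per patient, so cohorts are reproducible byte for byte.

What passing on this cohort shows: the pipeline recovers a planted
text-dominant signal (mean outer AUROC ≥ 0.95 for text-bearing modalities,
structured-only modalities far behind), discovers discriminative phrases
against a noisy proxy, assigns the published sign pattern to affirmation
versus family-history phrases, and is internally leak-free. What it does
not show: robustness to real clinical language — abbreviation diversity,
misspellings, section structure, copy-forward text — nor calibration on
real prevalences. The generator's grammar is deliberately narrow (a fixed
sentence pool keeps the n-gram vocabulary bounded); its separation is
cleaner than reality, which is why near-perfect synthetic AUROCs carry no
claim about performance on hospital data. One structural difference from
the published setting: with these prevalences the ICD screen is genuinely
more informative than the medication screen, so the two structured-only
modalities are not equivalent on synthetic data, whereas both were weak and
similar on the real cohorts.

## Problem sizes used in validation

The bundled validation runs are sized for a single CPU: planted-signal
recovery uses 2,000 notes with the search budget reduced to 15; cross-site
validation uses a stratified two-site sample (~600 notes per site, budget
10, 3 inner folds); the bootstrap-coverage study uses 200 simulations of
n = 300 at 500 resamples, checking 90–99% empirical coverage of a binormal
true AUROC; oracle-equivalence checks run hundreds of randomized instances
against exhaustive implementations. The acceptance script
(`scripts/acceptance.py`) re-runs all of these from scratch.

## Known limitations

- The lemmatizer is a small rule table, not a vocabulary-based lemmatizer;
  the Porter stemmer dominates the normalization anyway.
- "Error rate" in the extrapolation table is overall misclassification at
  the Youden cutoff; the published table does not distinguish false
  positives from false negatives.
- Whether one patient may contribute several sampled notes is left open;
  sampling permits repeats per patient, and patient-grouped folds contain
  the resulting correlation.
- The embedding path ships no pretrained weights; conclusions about real
  encoder quality are out of scope by design.
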