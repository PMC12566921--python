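# Methods

## Problem and pipeline

The package measures the use of negative patient descriptors in clinical
notes at two levels: per sentence (does this sentence use a keyword to
describe the patient negatively?) and per patient (does any note of this
patient contain such a descriptor, and how does that probability vary with
age group, race, insurance and pregnancy outcome group?). The stages run in
a fixed order: lexicon construction → sentence extraction and filtering →
annotation and classifier training → corpus classification → patient-level
analysis. Every stage is deterministic under a single global seed that fans
out to per-stage seeds by stable hashing, so a rerun of the same
configuration is byte-identical.

## Lexicon

The seed list is 15 keywords (nonadherent, aggressive, agitated, angry,
challenging, combative, noncompliant, confront, uncooperative, defensive,
exaggerate, hysterical, unpleasant, refuse, resist). Each keyword is
reduced to a **root**: the longest prefix shared with its grammatical
variant family (`aggress` for aggressive/aggression/aggressor). The default
variant table ships in-package and is overridable; roots are always a
prefix of their keyword, so matching the root always matches the keyword.

The **frequency-replacement rule** substitutes each keyword with the most
corpus-frequent token sharing its root (ties break toward the seed; a root
with no corpus matches keeps its keyword). The rule is idempotent for a
fixed corpus.

**Embedding expansion** trains two Word2Vec models — skip-gram and CBOW
with negative sampling — on the note sentences, window 5 and minimum count
1 (every token enters the vocabulary). Vector dimension (default 100;
the demo pipeline uses 50), epochs (default 10; demo 3), negative samples
(5) and the per-keyword neighbour count top_k (default 15) are
conventional small-corpus settings, all configurable. The trainer is
implemented in-package in numpy: single-threaded vectorized minibatch SGD
with a linearly decaying learning rate, unigram^(3/4) negative-sampling
table, and a seeded generator for initialization, shuffling and sampling —
chosen so that identical inputs give bit-identical vectors. Candidates
from both models are pooled, deduplicated keeping the maximum cosine
similarity, and ranked; increasing top_k never removes a candidate.

**Validation** is a two-reviewer ledger (CSV: term, reviewer_a,
reviewer_b); only dual-accepted candidates enter the final matcher
vocabulary, which is the set of roots plus validated exact terms.

## Sentence processing

Notes are segmented by a rule-based, abbreviation-aware splitter (terminal
punctuation followed by whitespace, except after known clinical
abbreviations or single-letter initials; decimals never split). Tokens are
lowercase maximal alphanumeric runs with internal hyphens kept, matching
the unit root-prefix matching operates on.

The length filter retains sentences with 3–27 tokens inclusive ("fewer
than three" and "more than 27" words excluded). In percentile mode the cap
is the **nearest-rank** 95th percentile of corpus token counts — nearest
rank rather than interpolation because token counts are integers and the
choice must be reproducible; the fixed-27 and percentile modes agree
whenever the corpus 95th percentile is 27.

A token is a keyword hit when its lowercase form starts with a lexicon
root or equals a validated term; hits carry character offsets and are, by
construction, equivalent to a brute-force regex scan (property-tested).

De-duplication normalizes by casefolding, stripping digits and collapsing
whitespace (so age-templated boilerplate collapses to one key), keeps one
representative of any normalized group repeated at least
`dedup_min_repeats` times (default 10 — the reference analysis reports
removing "common" sentences without stating a threshold), and removes
whitelist-matching clearly-non-negative templates ("a pleasant
NN-year-old… patient"). No automated negation detection is applied at this
stage; negated uses are handled by annotation labels downstream.

Annotation batches are drawn stratified by matched keyword (slots spread
as evenly as possible across keyword groups, remainder round-robined in a
seeded order), prioritizing diversity of keyword context.

## Annotation

Each sentence gets one of three labels: negative descriptor, not a
negative descriptor, out-of-context. Disagreement handling is
conservative: if exactly one reviewer chose *negative descriptor*, the
sentence is relabeled out-of-context and excluded from modeling;
a not-negative vs out-of-context split resolves to out-of-context without
exclusion, because no descriptor-presence dispute exists. Cohen's κ uses
marginal-product expected agreement; the degenerate case p_e = 1 (both
raters constant and identical) is defined as κ = 1 and logged. Agreement
is reported on the binary presence dimension by default — that is the
dimension the exclusion rule operates on — with the generic multi-class
statistic available. The modeling split is 80/20, label-stratified,
with 5 balanced CV folds, all seeded.

## Classifier

Features are whole-sentence binary unigrams + bigrams with minimum
document frequency 2 (counts and tf–idf, and a token window around hits,
are available). The vocabulary is fit on training sentences only; unseen
test n-grams map to nothing, so leakage is impossible by construction.

The primary model is logistic regression with an elastic-net penalty
(mixing parameter searched over {0.2, 0.5, 0.8}, inverse regularization C
over {0.01, 0.1, 1, 10}); baselines are plain L2 logistic regression,
random forest and an RBF SVM. Model selection maximizes mean 5-fold CV
AUROC; exact ties break toward stronger regularization. Linear models use
grid search; RF/SVM use a seeded Gaussian-process expected-improvement
search (Matérn 5/2, 5 random initial points, 15-evaluation budget) over
log-scaled bounds — a deliberately small, deterministic Bayesian
optimizer.

Evaluation reports AUROC, sensitivity, specificity, PPV, NPV, F1, accuracy
and AUPRC at decision threshold 0.5 (configurable), with 95% percentile
bootstrap intervals over test items (default 1,000 resamples, seeded; the
demo pipeline uses 200). A single-class test vector leaves the rank
metrics absent with a warning rather than fabricating them. Corpus
classification assigns every unlabeled keyword sentence a probability and
hard label; a tokenless sentence is labeled not-negative with a warning.
The error audit groups false positives and false negatives by matched
keyword and ranks keywords by FN count.

## Cohort statistics

Case = any severe-maternal-morbidity code (a configurable code set; the
shipped default is a three-code placeholder for the CDC indicator list,
which users supply) **or** readmission within 42 days, day 42 inclusive
("within 42 days"). A non-case with low birthweight (<2,500 g), preterm
delivery (<37 weeks), instrument-assisted delivery or NICU admission is
excluded from the cohort rather than kept as a contaminated control.

Rollups aggregate sentence labels to notes (keyword note = any sentence
with a hit; descriptor note = any sentence labeled negative-descriptor)
and patients (`has_descriptor` = at least one descriptor note), enforcing
n_descriptor ≤ n_keyword ≤ n_notes.

The stratified prevalence table restricts to patients with at least one
keyword note and reports column counts and one-decimal percentages with a
χ² test per axis, without continuity correction; a 2×2 axis with any
expected cell below 5 switches to Fisher's exact test, and larger sparse
axes keep χ² but carry a small-cell flag (no exact test for r×2 tables is
attempted). Odds-ratio models use the **full cohort** as denominator, with
patients lacking keyword notes counted as descriptor-free — the
patient-level question is cohort-wide, and restricting to keyword patients
would condition on an intermediate outcome. Unadjusted ORs come from
single-covariate logistic fits (exactly the 2×2 cross-product ad/bc on
binary exposures, verified to 1e-6), adjusted ORs from the joint fit over
age group, race, insurance and outcome group with references 45+, White,
Commercial, control. Levels with constant outcomes are flagged
non-estimable instead of reporting a runaway estimate; p-values carry
band markers at 0.1 / 0.05 / 0.01 / 0.001.

## Synthetic corpus generator

The generator is the test bench: it emulates the *structure* of a
maternal-care EHR extract, not clinical language. Demographic mixes
default to the reference cohort's marginals (race 0.60/0.20/0.20
Black/White/Other; age 0.43/0.55/0.02; insurance 0.53/0.44/0.03; case
fraction 7.5%). Descriptor presence is a per-patient Bernoulli draw from a
logistic model: the reference profile has probability
`descriptor_base_rate` (default 0.05, near the reference cohort's
patient-level descriptor prevalence) and each non-reference level
multiplies the odds by its configured true OR (defaults taken from the
reference adjusted estimates: Black 2.05, Medicare/Medicaid 1.59, case
1.40, younger ages ≈0.67). Because axes are sampled independently and the
outcome is rare, marginal 2×2 ORs collapse to the conditional ones within
Monte-Carlo error; calibration is property-tested (median sample OR over
200 replicates of n = 5,000 within ±10% of a true OR of 2.0).

Notes are assembled from template banks: neutral filler, heavily repeated
boilerplate ("patient was alert and cooperative", "a pleasant NN-year-old
… patient"), negated keyword uses, out-of-context keyword uses,
historical-mention keyword variants, and descriptor sentences injected
only for flagged patients — so a patient's true flag equals the OR over
sentence truths by construction. Injected sentence classes take optional
trailing phrases so they vary lexically the way real notes do rather than
collapsing to a handful of normalized keys. Truth labels are recorded at
injection time, never inferred. Outcome records are sampled so the
case/control rules recover each patient's intended group exactly.

Defaults that are scale choices rather than emulated quantities: notes per
patient 1 + Poisson(3) and sentences per note 1 + Poisson(5) (the
reference corpus implies ~20 notes/patient but no distribution; the
package default keeps desk-scale corpora tractable and both are config),
negation/out-of-context injection at 10% of sentences each,
boilerplate at 25%, historical variants at 3%.

What passing tests on this corpus do **not** show: robustness to real
clinical language (spelling noise, copy-forward, section headers, rich
negation scope), to lexicon drift across sites, or to annotation ambiguity
— template-generated sentences are far more separable than real ones, so
demo classifier metrics (AUROC ≈ 1) are an upper bound, not a forecast.
Classifier metrics reported for real cohorts elsewhere are therefore not
reproduction targets for this package.

## Numerical and design choices

- Length-filter boundaries inclusive; day-42 readmission boundary
  inclusive.
- Frequency-replacement ties break toward the seed keyword, then
  lexicographically.
- CV tie-breaks prefer stronger regularization (smaller C, then larger L1
  mix; shallower forests).
- Bootstrap intervals are percentile (2.5/97.5); degenerate resamples with
  a single class contribute NaN rank metrics and are excluded via
  nan-percentiles.
- Seeds derive from the global seed as the first four bytes of
  SHA-256("seed:stage"), keeping every derived seed below 2³¹.
- Degenerate inputs: empty corpora raise configuration/input errors rather
  than returning empty statistics; empty strata are dropped from χ² with a
  warning; kappa on constant identical raters returns 1.

## Known limitations

No clinical-section detection, spelling normalization or copy-forward
detection; no automated negation detection (annotation handles negation);
no third-reviewer adjudication workflow; Medicare and Medicaid are not
disaggregated; the severe-maternal-morbidity code list is a user-supplied
configuration, not a curated clinical artifact; contextual/transformer
embeddings and LLM classifiers are out of scope.
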