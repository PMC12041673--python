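# Methods

This note documents the models and procedures implemented in `diatraj`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## The prediction problem

Each patient is an ordered sequence of hospital visits; a visit carries a
decade-of-life age-range label and a set of chronic ICD-9-derived diagnosis
codes. All patients have diabetes (code 401); the task is to predict, from
the visits that follow diabetes onset, whether a patient will develop one of
four complications — retinopathy (703), chronic kidney disease (1401),
ischemic heart disease (910), amputation (1999) — before that complication is
recorded. The problem is decomposed into four independent binary tasks rather
than one multi-label task, so each complication's predictors can be read
directly off its own model.

## Cleaning cascade

The raw dialect tolerates structural noise: empty visits, visits holding only
an age label, missing or misplaced age labels, repeated chronic codes,
records without a gender or with both genders, records consisting only of the
gender token, records without the diabetes code, visits predating diabetes,
and complications recorded before diabetes. The cascade is:

1. record-level filters (empty → gender missing/conflicting → gender-only →
   no diabetes code), applied in that order so each removal has one cause;
2. per-visit normalization: empty and age-only visits become null; the first
   age token found anywhere in the visit becomes its label (extras are
   dropped with a warning — the case is undocumented in the source
   conventions and assumed to be noise); codes sort ascending by integer
   value;
3. null compaction plus chronic-code deduplication (first appearance wins),
   iterated to a fixpoint because deduplication can empty a visit;
4. age imputation: a missing label takes the next later visit's label, a
   missing tail label takes the previous one; records with no labels at all
   are removed;
5. diabetes anchoring: records whose first complication occurrence precedes
   the first diabetes visit are removed; remaining pre-diabetes visits are
   dropped so the diabetes visit is visit 1; a final compaction pass follows.

Deduplication deliberately precedes pre-diabetes visit dropping (the literal
reading of the source's enumerated steps). The consequence — verified by a
dedicated test — is that a chronic code seen both before and after onset
disappears entirely: its first appearance is pre-diabetes and leaves with its
visit. The alternative order would instead retain the post-onset occurrence;
this is the single most consequential ambiguity in the procedure and is fixed
here, once, in the order stated.

The cascade is idempotent and audited: the cleaning report reconciles exactly
(records in = records out + removals per rule), and output records are
validated against the cleaned-record invariants (resolved, non-decreasing age
labels; ascending, globally unique codes; diabetes at visit 1).

## Endpoint datasets and leakage control

A positive instance keeps the visits strictly before the endpoint's visit.
The *entire* endpoint-bearing visit is dropped, not just the endpoint code:
co-diagnoses recorded simultaneously with the outcome are future information.
This is the stricter of the two defensible windowings and is the default;
the temporal threshold (minimum visits between onset and complication) is
exposed as `min_gap_visits`, default 1. Negatives drop exactly their last
visit — uniformly, even when that visit holds another endpoint — so both
classes end one visit short of the information that decided their label.
Endpoints at visit 1 and single-visit negatives are excluded.

Balancing keeps all positives and samples negatives uniformly without
replacement to the positive count, with a recorded seed. The positive
multiset is therefore seed-invariant; only negative selection varies.

## Feature encodings

**Pair encoding.** The vocabulary is the k distinct (age label, code) pairs
observed across instance windows, ordered numerically. An instance maps to a
(k + 2)-vector: each pair slot holds the 1-based index of the window visit
containing the pair (0 when absent), so later visits receive larger raw
weights; two slots one-hot the gender. The linear 1..V visit index is the
minimal order-based weight consistent with the source description, which
names order weights but no formula. Because codes are deduplicated upstream,
each pair occurs in at most one visit and the map pair → visit index is
recoverable from the raw vector.

**Normalization.** Per-column min-max to [0, 1], fitted on the training rows
of each split and applied (with clipping) to evaluation rows; constant
columns map to 0. Fitting on the full dataset before splitting would be the
literal replication but leaks evaluation information; the leakage-safe scope
is the default and the fit rows are recorded so tests can assert it. A
whole-dataset scope remains available by passing all rows as fit rows.

**Bag-of-Features baseline.** Individual codes, individual age labels and
gender as independent count features (ages count once per visit bearing them;
codes at most once after deduplication), min-max scaled under the same
contract. With the default 83-code vocabulary this is ≤ 95 features.

**Document frequency.** DF% of a pair is the percentage of positive
instances whose window contains it; diabetes-code pairs are excluded since
the code is present in every record by construction.

## Classifiers, ranking and validation

Five families: decision tree, random forest, XGBoost, AdaBoost (scikit-learn
and xgboost implementations) and LogitBoost, written in-package as stagewise
additive logistic boosting — each round fits a depth-2 regression tree to the
Newton working response z = (y − p)/(p(1 − p)) with weights p(1 − p) and
updates the additive logit by a 0.1 learning rate. Defaults everywhere are
the common library conventions (100 trees/rounds, depth 6 for XGBoost,
unlimited-depth decision tree), all overridable per model spec.

Feature ranking fits an XGBoost model on training rows and orders features by
total gain; zero-gain features follow all positive ones in feature-id order,
making the ranking a deterministic total order.

**MCCV** repeats stratified 90/10 splits (stratification keeps balanced test
sets so accuracy and AUC stay comparable; on balanced test sets accuracy
equals (sensitivity + specificity)/2, asserted per run). Each of
K × repetitions runs re-randomizes the split — the reading chosen for the
ambiguous "repetitions per subset size" — and normalizer, ranking and models
are refitted inside every split. **Partitioned validation** allocates
floor(0.05 N) rows to each of five disjoint stratified validation subsets
(largest-remainder rounding per class) and trains once on the remainder;
this floor-plus-remainder arithmetic reproduces the published partition
tables exactly and is the reason training sets are marginally larger than
75%. AUC is the normalized Mann-Whitney statistic with half-credit ties,
equal to trapezoidal ROC integration; undefined quantities (single-class
subsets, empty prediction denominators) are reported as NaN rather than
silently zeroed.

Seeding fans the master seed out through a `SeedSequence` counter scheme —
one child per run, providing the split seed, ranking seed and one model seed
per family — so any single run is reproducible in isolation, and all derived
seeds stay below 2^31.

## Synthetic cohort generator

The generator emulates the trajectory dialect at the scale of the real
corpus: 83 diagnosis codes, 10 age labels, gender in the first visit, a
truncated-geometric visit-count law (mean ≈ 3, max 11), onset ages
concentrated in the 40–80 decades, and per-visit code inclusion from an
age-dependent prevalence table (ten "archetype" chronic codes whose
prevalence climbs with age over a flat background). Diabetes is assigned at
the onset visit (visit 1 in clean generation). Endpoints follow a per-visit
logistic hazard: from visit 2 on, the event probability is
logistic(intercept + Σ coefficients over the (age, code) pairs accumulated in
*prior* visits). Exposure through pairs makes the pair features the
Bayes-relevant predictors by construction, so feature-recovery tests are
meaningful. Defaults plant 10 risk pairs per endpoint (late-decade archetype
pairs, coefficient 2.0, intercept −5), values chosen once as a realistic
moderate-effect regime; empirical incidence matches the closed-form model
within binomial error by test.

Structural noise is injected after clean generation and recorded per patient.
Record-removing anomalies (gender missing/conflicting/only, missing diabetes,
endpoint-before-diabetes) are mutually exclusive per patient so cleaning
removals reconcile with planted counts exactly; benign anomalies (empty and
age-only visits, missing/misplaced age labels, duplicated chronic codes,
pre-diabetes visits) are drawn independently and constrained to remain
benign (e.g. an age label is only stripped from a visit that survives
deduplication, so the record cannot silently become removable).

What the generator does **not** emulate: the deep generative model behind
the real corpus, correlations between comorbidities beyond shared age
gradients, informative visit timing, censoring, or code-frequency
distributions calibrated to the published marginals. Passing tests therefore
demonstrate the pipeline's correctness and its ability to recover planted
temporal pair signal — not clinical performance on real records, whose
published metric values are data-dependent and out of scope here.

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down study conditions
chosen to exercise every code path with stable statistics: cohorts of
2,000–5,000 patients for filter exactness and signal recovery, 1,000
instances and 20 splits for the permuted-label null check, 10 seeds for
seed-averaged recovery, and K = 3–10 MCCV repeats per configuration.
Classification threshold is fixed at 0.5 on balanced data. Ranking ties
break by ascending feature id; subset sizes larger than the feature
dimension are capped with a warning. Moments in summary tables use the
spreadsheet conventions (ddof = 1; bias-corrected skewness and excess
kurtosis) and report NaN when undefined.

## Known limitations

* LogitBoost is a Newton-style gradient implementation of additive logistic
  boosting, not a line-by-line reproduction of any particular historical
  variant.
* The JSON dialect (positional arrays of token strings) is fixed by this
  package; a keyed on-disk variant of the real corpus would need a second
  reader.
* Per-patient identifiers are file positions; there is no patient linkage
  across cohorts.
* No ICD-9 hierarchy or semantic grouping: codes are opaque tokens.
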