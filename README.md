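# diatraj

Risk prediction of diabetes complications from coded electronic-health-record
visit trajectories.

Patients with diabetes develop serious long-term complications — retinopathy,
chronic kidney disease, ischemic heart disease, amputation — whose early
symptoms are easy to miss. Their diagnosis trajectories, however, are routinely
recorded: each hospital visit carries a decade-of-life age-range label and one
or more chronic ICD-9-derived diagnosis codes. `diatraj` turns such coded visit
sequences into per-complication binary prediction tasks and evaluates tree
ensemble classifiers on them. It is aimed at biostatisticians and clinical
ML researchers who want a fully testable version of this kind of trajectory
pipeline, including a synthetic cohort generator with *known* planted risk
structure so every stage can be validated without access to patient data.

## The data model

A cohort is a JSON array of patients; a patient is an array of visits; a visit
is an array of integer-coded string tokens:

* gender: `"1111"` (male) / `"2222"` (female), coded in the first visit;
* age-range label per visit: `"1000"` (&lt;10) … `"1090"` (&gt;90);
* chronic diagnosis codes (83 distinct), with diabetes `"401"` and the four
  complication endpoints `"703"` (retinopathy), `"1401"` (chronic kidney
  disease), `"910"` (ischemic heart disease), `"1999"` (amputation).

## The method

1. **Cleaning cascade** — remove records that are empty, have missing or
   conflicting gender, contain only the gender token, or lack the diabetes
   code; null out empty and age-only visits; put the age label first and sort
   codes ascending within each visit; compact null visits; keep only the first
   appearance of each chronic code; impute missing age labels from the next
   later visit (previous at the tail); drop records whose complication
   precedes diabetes; drop all pre-diabetes visits so the diabetes visit is
   visit 1.
2. **Endpoint datasets** — for endpoint *e*, a record whose endpoint first
   appears at visit *v* ≥ 2 becomes a positive with input window visits
   1..*v*−1; endpoint-free records become negatives with the last visit
   dropped. Endpoints at visit 1 and single-visit negatives are excluded.
   Negatives are downsampled (seeded, without replacement) to the positive
   count.
3. **Feature encoding** — the vocabulary is the *k* distinct (age-range,
   code) pairs observed in the dataset; each instance becomes a
   (*k* + 2)-vector whose pair slots hold the 1-based index of the visit
   containing the pair (later visits ⇒ larger weights) plus two gender
   indicators, min-max scaled per column to [0, 1] on training rows only.
   A Bag-of-Features baseline (independent code/age/gender counts, &lt;100
   features) is provided for comparison, as is a positive-class document
   frequency (DF%) table of the most common pairs.
4. **Feature selection and models** — features are ranked by total gain of a
   gradient-boosted tree fit; decision tree, random forest, XGBoost, AdaBoost
   and LogitBoost classifiers are trained on the top-*k* subsets
   (25/50/100/150/200/all).
5. **Validation** — Monte-Carlo cross-validation (repeated stratified 90/10
   splits, metrics averaged) and partitioned validation (a stratified 75%
   training allocation with five disjoint 5% validation subsets scored
   separately). The metric panel is accuracy, sensitivity, specificity,
   precision, F-measure and rank-statistic AUC.

## Worked example

```python
from diatraj import (SimConfig, generate_cohort, preprocess_cohort,
                     build_endpoint_dataset, document_frequency,
                     EvalConfig, ModelSpec, run_mccv, default_codebook)

cb = default_codebook()
cohort, truth = generate_cohort(SimConfig(n_patients=3000, seed=11))
records, report = preprocess_cohort(cohort, cb)
print(f"cleaned records: {report.records_out}/{report.records_in}")

dataset, excluded = build_endpoint_dataset(records, "910", seed=17)
print(f"endpoint 910: {dataset.n_positive} positives, "
      f"{dataset.n_negative} negatives, {len(excluded)} excluded")

print(document_frequency(dataset, cb, top_n=5).to_string(index=False))

config = EvalConfig(k_repeats=5, repetitions=1,
                    feature_subset_sizes=(50, "all"), seed=3)
result = run_mccv(dataset, [ModelSpec("xgboost"),
                            ModelSpec("random_forest")], config)
print(result.summary().round(3).to_string(index=False))
```

Output:

```
cleaned records: 3000/3000
endpoint 910: 486 positives, 486 negatives, 1007 excluded
age_range code    df_pct
     1060  914 27.777778
     1060 1302 27.777778
     1060  402 26.337449
     1060  913 26.131687
     1050  913 20.781893
       family subset_size  accuracy  sensitivity  specificity  f_measure  precision   auc
      xgboost          50     0.804        0.808        0.800      0.805      0.804 0.862
random_forest          50     0.786        0.812        0.759      0.791      0.775 0.851
      xgboost         all     0.806        0.812        0.800      0.807      0.804 0.863
random_forest         all     0.784        0.833        0.735      0.794      0.762 0.850
```

A zero-noise synthetic cohort passes the cascade untouched (3000/3000). After
windowing and balancing, the ischemic-heart-disease task has 486 instances
per class; 1007 records were excluded (mostly single-visit negatives). The DF
table shows the planted late-decade comorbidity pairs (heart failure 914,
hypertension 913, hyperlipidaemia 402, arthrosis 1302 in the 50–70 decades)
dominating the positive class, and both ensembles recover the planted signal
(AUC ≈ 0.85–0.86). Feature selection to 50 of the ~500 pair features loses
essentially nothing — the planted risk structure is 10 pairs.

The same pipeline is available from the shell:

```bash
diatraj simulate --n-patients 3000 --seed 11 --out cohort.json
diatraj preprocess --in cohort.json --out clean.json --report report.tsv
diatraj build --endpoint 910 --in clean.json --out ds910.json --seed 17
diatraj evaluate --dataset ds910.json --protocol mccv --k 5 \
    --subsets 50,all --models xgb,rf --seed 3 --out mccv.tsv
```

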