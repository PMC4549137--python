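# scaconn

Whole-brain resting-state functional-connectivity analysis and
patient/control classification for spinocerebellar ataxia type 7 (SCA7)
cohorts — as a tested, reusable Python library.

SCA7 is a rare polyglutamine ataxia (CAG-repeat expansion in *ATXN7*)
with well-documented cerebellar and visual-system degeneration.
Resting-state fMRI studies of such cohorts ask two questions this package
operationalizes end to end:

1. **Which connections differ?** Parcellate the brain into R = 116
   regions (AAL atlas: 45 bilateral cortical, 9 bilateral cerebellar,
   8 vermis regions), compute the Pearson correlation r_ij between every
   pair of regional time courses, and compare patients with controls
   edge-by-edge using two-tailed two-sample t-tests; edges with
   p < 0.001 (uncorrected — it is a feature-selection step, not an
   inference) form the abnormal-connectivity pattern.
2. **Do those connections discriminate?** Feed the selected edges to a
   linear soft-margin SVM trained by sequential minimal optimization
   (SMO, implemented in this package) and estimate accuracy, sensitivity
   (patients correctly classified) and specificity (controls correctly
   classified) by stratified 10-fold cross-validation.

Because raw clinical fMRI is rarely shareable, the package starts at ROI
time series + rigid-body motion parameters (tabular text) and ships a
synthetic-cohort generator with known connectivity ground truth: group
differences are planted at designated edges as signed correlation offsets,
with nuisance structure (drift, shared low-frequency confound, noise,
motion spikes) and clinical covariates linearly coupled to one edge.
Every pipeline stage is therefore testable against ground truth, including
two properties no single-dataset study can check: **null calibration**
(false-positive rate of the edge filter) and **selection leakage** (how
much accuracy is inflated when features are selected on all subjects
before cross-validation — the protocol many published studies describe —
versus inside each training fold).

## Pipeline

```
ROI time series + motion  ──►  detrend ─ band-pass 0.01–0.08 Hz ─ global-signal
                               regression ─ censor frames (FD > 0.5 mm,
                               signal change > 0.5%)
                          ──►  116×116 Pearson matrix ─ 6670-edge vector
                          ──►  edge-wise t-tests ─ select p < 0.001 ─ direction
                               (increase/decrease) ─ edge–behavior correlations
                          ──►  linear SVM (SMO) ─ stratified 10-fold CV ─
                               accuracy / sensitivity / specificity
```

## Worked example

`examples/` contains one short script per capability. Generating a
study-scale cohort (26 patients / 26 controls, 19 perturbed edges at
|Δr| = 0.3) and cross-validating the classifier:

```bash
$ python examples/04_classification.py
nested: accuracy  98.1%  sensitivity  96.2%  specificity 100.0%  (25+26 of 52 correct)
pooled: accuracy  98.1%  sensitivity  96.2%  specificity 100.0%  (25+26 of 52 correct)
```

With true edge effects present both protocols succeed. On *null* cohorts
(no group difference) only the nested protocol is honest:

```bash
$ python examples/05_selection_bias.py
edge-wise rejections at p<0.001: 2 of 1900 tests (nominal 0.001)
nested CV accuracy (mean over seeds): 51.3%
pooled CV accuracy (mean over seeds): 80.2%
selection-bias inflation: +28.8 percentage points
```

The edge filter is well calibrated (2/1900 ≈ 0.001), nested accuracy sits
at chance, and selecting edges before cross-validation manufactures ~80%
"accuracy" from pure noise — which is why both protocols are first-class
here and the honest one is the default.

The same machinery exposes the group-statistics table (a published-style
abnormal-connections listing with AAL region names, t, p and
increase/decrease direction — `examples/03_edge_statistics.py`) and
edge–behavior Pearson correlations with the SARA ataxia score, CAG repeat
count and symptom duration over patients.

A thin CLI mirrors the stages:

```bash
scaconn generate --seed 1 --out cohort/
scaconn classify cohort/ --mode nested --k 10 --threshold 0.001 --seed 1
scaconn run-all --config config.yaml --out experiment/
```

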