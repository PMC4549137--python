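# Methods

This note documents the models, defaults and design choices behind
`scaconn`, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and input contract

The package operates on ROI-level data: per-subject T×R time-series
tables (T volumes, R regions, repetition time TR in a JSON sidecar) and
T×6 rigid-body motion-parameter tables. Image-space preprocessing (brain
extraction, realignment estimation, smoothing, spatial normalization,
parcellation of voxel images) belongs to external neuroimaging tools and
is deliberately out of scope; the packaged AAL-116 label table fixes
region identity and ordering for all matrices and edge indices.

## Temporal preprocessing

Applied per region, in a fixed order:

1. **Linear detrending** — OLS line (intercept + slope) removed.
2. **Band-pass 0.01–0.08 Hz** — the canonical resting-state BOLD band.
   Realized as an order-4 Butterworth applied forward–backward
   (`filtfilt`), i.e. zero-phase, so temporal features are not shifted.
   The filter family is a package choice (standard rsfMRI practice); the
   testable contract is spectral: amplitude ratio ≥ 0.9 at 0.04 Hz and
   ≤ 0.1 at 0.005 Hz for TR ∈ {1, 2, 3} s.
3. **Nuisance regression** — OLS residual on [intercept | confounds].
   At ROI level the global mean signal is the mean across regions;
   white-matter/CSF traces can be supplied as extra confound columns.
   Rank-deficient confound matrices are rejected naming the collinear
   columns.
4. **Motion censoring** — frame-wise displacement
   FD(t) = Σ|Δtrans| + 50 mm · Σ|Δrot| (arc length on a nominal 50 mm
   head sphere; FD(0) = 0), plus a DVARS-like per-volume RMS percent
   signal change. Frames with FD > 0.5 mm or signal change > 0.5% are
   discarded. One published description of this rule reads, literally,
   as discarding *low*-change volumes; the conventional exceedance rule
   is implemented as the default and the literal reading is available
   behind `CensoringPolicy(censor_low_change=True)`. Percent change is
   evaluated on the raw series (where the signal baseline still exists;
   a demeaned series has no meaningful "percent"), with an RMS-amplitude
   fallback for near-zero-mean regions. Fewer than 30 surviving frames
   is an error.

Censoring runs last so the filter never operates across excised frames;
correlations downstream use kept frames only (listwise deletion).

## Connectivity and edge indexing

Functional connectivity is the sample Pearson correlation over kept
frames; the R×R matrix is symmetric with unit diagonal. The canonical
edge order is lexicographic over pairs (i, j), i < j — the same edge set
as the lower triangle, R(R−1)/2 = 6670 edges at R = 116. Raw r is the
default feature value; the Fisher transform z = atanh(r) is available by
flag but off by default. Zero-variance regions (including
numerically-zero residue after preprocessing) are an error naming the
region.

## Group statistics and selection

Edge-wise two-tailed two-sample t-tests compare patients and controls.
The default is the pooled-variance Student test (df = n₁ + n₂ − 2);
with equal group sizes the Welch alternative (available by flag) is
nearly identical, a property the suite checks. Selection keeps edges
with p strictly below 0.001, uncorrected — deliberately, because it is a
feature-selection step; the expected false-positive count
(threshold × number of edges) is reported alongside as context. Output
ordering is (p, edge id), deterministic. Edge–behavior associations are
Pearson correlations over patients only (controls carry no severity
scores), with two-tailed p from the t approximation on df = n − 2.

## Classifier

Linear soft-margin SVM trained in-repo by SMO with maximal-violating-pair
working-set selection: the pair of dual multipliers most violating the
KKT conditions is optimized analytically each iteration, with the weight
vector maintained incrementally (linear kernel), until no pair violates
beyond `tol` (default 1e−3). The bias is the midpoint of the interval
the KKT conditions permit — exact when free support vectors exist,
deterministic otherwise. C defaults to 1.0: features are correlations
bounded in [−1, 1], so no standardization is applied by default.
Decision ties (f(x) = 0 exactly) map to the patient class. The test
suite pins the solver to a brute-force QP solution (SLSQP on the dual)
within 1e−4 in objective on ≤ 12-sample problems and cross-checks w and
b against an independent reference implementation.

Cross-validation is stratified 10-fold by default (fold sizes within 1,
class counts per fold within 1 of proportional; deterministic given the
seed; unstratified available by flag). Two selection protocols are
first-class:

* **nested** (default) — edge selection re-run inside each training
  fold; a fold whose training selection is empty is skipped with a
  recorded warning.
* **pooled** — selection once on all subjects before CV. This mirrors
  the protocol as commonly described in connectivity-classification
  studies and exists expressly so its optimism can be measured.

Metrics are micro-averaged (confusion counts pooled over folds before
computing accuracy, sensitivity, specificity): with 5–6 subjects per
fold, per-fold rates are too unstable to average. Raw pooled counts are
reported alongside percentages, since a percentage like "95% of 26
patients" does not correspond to an integer count and the rounding
convention of any given study is unknowable.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not fMRI physics. Per subject, the latent signal is a multivariate
normal draw with a block-structured target correlation matrix (defaults:
4 near-equal blocks, within-block r = 0.3, between-block r = 0.05),
AR(1)-smoothed in time (ρ = 0.3; linear and identical per region, so the
cross-regional correlation structure is preserved while frame-to-frame
changes stay realistically small). On top: baseline 1000 a.u. (sets the
percent-signal-change scale), signal SD 2.5, white noise SD 1.0, random
linear drift (slope SD 0.02 units/volume), a shared sinusoidal confound
(amplitude 1.5, frequency 0.01–0.03 Hz) entering all regions equally —
removable by global-signal regression. These amplitudes are calibrated
once so typical frames sit below the 0.5% DVARS threshold while spike
artifacts clearly exceed it. Motion spikes (per-volume probability 0.02)
are step displacements of 2 mm (the head moves and stays, so FD flags
one frame) paired with a one-frame 10 a.u. amplitude artifact in all
regions (which DVARS flags at the pulse and its return).

Patient and control target matrices differ exactly at designated edges,
shifted by signed offsets; since arbitrary edge edits can break positive
semidefiniteness, the patient matrix is repaired by alternating
projections onto the PSD cone and the unit-diagonal set (Higham-style
nearest correlation matrix, eigenvalue floor 1e−6). The study-scale
default plants 19 edges at the positions of the reported abnormal
connections with |Δr| = 0.3 — the magnitude is a free parameter of the
simulation, since published tables report p-values, not correlation-scale
effect sizes. Clinical covariates (SARA, symptom duration) are linear in
the measured raw-series connectivity of one designated edge (the left
middle frontal – right superior frontal pair) with negative slope plus
Gaussian noise, clipped to legal ranges (SARA ∈ [0, 40]); intercepts are
set so covariates land in plausible clinical ranges given that edge's
realized connectivity (~0.64 on the raw series).

Per-subject seeds derive from (master seed, subject index) via
`numpy.random.SeedSequence` spawn keys — counter-based, so any subject's
data are reproducible independent of generation order.

**What passing tests do and do not show.** The generator's Gaussian,
stationary, temporally-simple signals validate the *statistical* pipeline
— calibration, power, leakage, determinism — under conditions where
ground truth is known. They do not certify performance on real BOLD data
(non-Gaussian noise, physiological rhythms, spatially structured
artifacts, atlas misregistration), and the classifier accuracies obtained
on synthetic cohorts are properties of the chosen effect size, not
estimates of any clinical study's accuracy.

## Study-scale experiments and problem sizes

`scaconn.experiments` packages three repeated-cohort studies, each run
with 20 replicate seeds by default:

* **Null calibration** — 26/26 subjects, 120 volumes, 20 regions
  (190 edges), zero perturbed edges: edge-wise rejections at p < 0.001
  are tested for binomial compatibility with the nominal rate, and
  nested-protocol CV accuracy is checked to sit within 0.1 of chance.
  The 20-region profile keeps replicate counts high at negligible cost;
  calibration is per-edge and does not depend on R.
* **Recovery** — full study scale (26/26, 116 regions, 19 perturbed
  edges, |Δr| = 0.3): fraction of ground-truth edges selected at
  p < 0.001 (required ≥ 70% on average — a repository property, not a
  literature claim), the selection rate among unperturbed edges, and
  nested CV accuracy (required > 0.8).
* **Leakage** — on the null cohorts, pooled-protocol accuracy is
  compared with nested per seed. Null-cohort CV uses a liberal selection
  threshold (p < 0.05): at p < 0.001 a null cohort selects no edges in
  most folds, leaving nothing to classify; the liberal threshold is what
  makes the leakage effect visible and is applied identically to both
  protocols. Edge-wise calibration stays at p < 0.001.

## Numerical choices and degenerate inputs

* Butterworth order 4; `filtfilt` default padding (T = 120 is ample).
* Zero-variance regions: error naming the region, with a relative floor
  (SD ≤ 1e−12 × data scale) so rounding residue counts as constant.
* t-tests with zero pooled variance: error, checked before the fit.
* Nearest-correlation repair: eigenvalue floor 1e−6, convergence
  tolerance 1e−10, hard failure (not silent) if not converged.
* SMO: deterministic; `eps` scales with C; flat-direction (duplicate
  point) subproblems jump to the better bound.
* Folds: per-class round-robin dealing with rotated remainders, so fold
  sizes and per-fold class counts both stay within ±1.
* Absent table values are empty cells, never 0 (0 is a legal SARA score).

## Known limitations

* No voxel-level or image-space processing; WM/CSF confounds only as
  externally supplied columns.
* No multiple-comparison correction, network-based statistics or
  graph-theoretic summaries — selection is deliberately the simple
  univariate filter.
* Linear kernel only; no hyperparameter search or probability
  calibration.
* The synthetic motion/artifact model is minimal (steps and pulses);
  real scanner motion is temporally correlated and spatially structured.
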