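# Methods

`eegrisk` models the path from a 19-channel resting-state EEG recording
to an individual risk estimate for post-stroke cognitive impairment
(PSCI). This note documents the model assumptions, the synthetic data
the pipeline is validated on, the numerical choices, and the known
limitations. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## The synthetic cohort generator

No public cohort of this kind exists, so the generator is a first-class
component rather than a fixture. A recording is rendered as

```
x[:, t] = m(label[t]) * e[t] + sigma * n[:, t]
```

* `label` — a microstate sequence with alternating segments: segment
  classes are drawn from per-class occurrence weights with no immediate
  self-transition; segment lengths are geometric (memoryless, truncated
  at one sample) with per-class mean durations in ms. The geometric law
  is the simplest one-parameter duration model; real microstate
  duration distributions are heavier-bodied, and nothing here depends
  on the exact law beyond its mean.
* `m(k)` — one of four canonical topographies. A and B are mirror-image
  diagonal scalp gradients whose axes sit 25° off the left–right axis,
  C is the anterior–posterior gradient, D a circularly symmetric
  vertex-centred profile; all are centred and unit-normalised. The 25°
  angle is a deliberate geometry choice: for any mirror pair the equal
  A+B mixture is exactly collinear with the anterior–posterior gradient
  C, so with axes near 45° every band-pass-blurred A↔B transition
  dwells in a C-like topography for tens of milliseconds, fragmenting
  backfitted segments even in noise-free data. At 25° all pairwise
  template correlations stay ≤ 0.62 and the dwell window falls below
  the 8 ms segment filter.
* `e` — a shared broadband envelope with unit RMS whose amplitude
  spectrum follows `f^(-alpha/2)` (default alpha = 1, pink power
  spectrum) multiplied by per-band **amplitude** gains (power scales
  with the gain squared). Amplitude gains are used because they give an
  unambiguous, monotone mapping from gain to band power regardless of
  band width. Envelope support is 1–40 Hz: inside the PSD analysis
  range and almost entirely inside the 1–35 Hz microstate band, so the
  microstate band-pass barely distorts rendered topographies at label
  switches; the delta gain therefore acts on 1–4 Hz.
* `n` — white Gaussian sensor noise; `sigma` is expressed relative to
  the unit-RMS envelope. Default 0.05.

Group defaults emulate an eyes-closed clinical cohort: the control
group has an alpha-bump (gains δ/θ/α/β/γ = 1/1/1.6/1.2/0.8, putting
global DTABR near 1) and mean durations 45/45/48/43 ms; the
impaired-like group has elevated slow-wave gains (1.5/1.4/1.2/1.0/0.8),
longer A/B durations (55/53 ms) and a reduced D occurrence weight —
the directions reported for PSCI. The `strong_effect` variant used in
validation doubles the control δ/θ gains, lengthens A/B durations by
40% and halves the D weight. Demographics (age ≈ round-normal(64, 8)
clipped to 40–80; sex Bernoulli 0.68 male) carry no outcome signal.
Amplitude units are arbitrary throughout: every downstream feature is a
ratio or a label statistic.

What the generator does **not** emulate: volume conduction and realistic
source mixing, ocular/muscle artifacts, non-stationarity, inter-subject
montage variability, and any correlation between demographics and
outcome. Passing tests therefore demonstrate correctness of the
*computations* and recoverability of *planted* effects, not clinical
performance on real EEG.

## Preprocessing

* Band-pass: zero-phase Butterworth via forward–backward filtering.
  "4th order" refers to the designed filter; the effective magnitude
  response is its square. Microstate analysis uses 1–35 Hz; spectral
  features are computed on the unfiltered common-average-referenced
  signal because a 1–35 Hz filter would destroy the 30–40 Hz gamma
  band.
* Common average reference: subtract the per-sample channel mean;
  idempotent; leaves GFP unchanged.
* Bad-channel repair: spherical-spline interpolation (order m = 4,
  regularisation λ = 1e-5, Legendre series truncated at 7 terms) on the
  unit sphere. The constraint formulation reproduces constant fields
  exactly; with only 19 electrodes, 7 series terms are sufficient
  (higher orders are unresolvable).
* Quality control: a recording is rejected when **more than** 20% of
  samples are flagged corrupted or **more than** 3 channels are
  nonfunctional; boundary values are accepted. The corruption mask is
  an input: component-based artifact removal requires visual
  inspection and is deliberately out of scope.

## Spectral features

Welch PSD with 4 s Hann segments and 50% overlap (0.25 Hz resolution at
any sampling rate), density scaling. Band powers are trapezoidal
integrals over half-open intervals [low, high) so adjacent bands never
double-count a grid frequency. Regional aggregation averages channel
band powers over the region *before* forming ratios (ratio of means).
Region sets: frontal = {Fp1, Fp2, F7, F3, Fz, F4, F8}, central =
{T3, C3, Cz, C4, T4}, posterior = {T5, P3, Pz, P4, T6, O1, O2},
global = all 19. All 12 ratios are scale-invariant by construction.

## Microstate analysis

* GFP is the per-sample *population* standard deviation across
  channels. Peaks are picked per 60 s segment independently with a
  10 ms minimum spacing (the larger of two close maxima survives) and a
  per-segment outlier ceiling of mean + 2 SD.
* Modified K-means operates on the spatially centred peak maps with
  polarity-invariant correlation (a map and its negation are the same
  state). The template update is the dominant eigenvector of each
  cluster's scatter matrix — polarity-proof, and automatically
  zero-mean because the maps are centred. Both the assignment and the
  update step maximise the same GFP²-weighted squared-correlation
  objective, so GEV is monotonically non-decreasing; iteration stops
  when the improvement drops below 1e-6 (max 500 iterations). Empty
  clusters keep their previous template.
* Initialization search: per-class candidate banks are parametric
  perturbations of the canonical maps — the gradient axis rotated over
  an evenly spaced ±30° fan (7/5/6/3 candidates for A/B/C/D; the D bank
  varies the radial decay exponent instead), giving 7×5×6×3 = 630
  one-per-class combinations. Every combination is run to convergence
  and the highest final GEV wins; ties keep the lexicographically
  smallest index tuple.
* Backfitting is per-sample winner-take-all on the 1–35 Hz signal (ties
  break A < B < C < D; zero-GFP samples fall to class A). This is
  simpler than peak-interpolation labelling and is a known divergence
  risk versus toolboxes that interpolate between peaks: per-sample
  relabelling fragments runs wherever the instantaneous envelope is
  small, so absolute backfitted durations sit well below the planted
  segment means. The cross-class *ordering* of durations — the carrier
  of the group effect — is preserved, which is what the recovery checks
  assert.
* Segments shorter than 8 ms or longer than 120 ms become unassigned;
  runs separated by an excluded gap are never merged. Statistics use
  the full analysis time (including unassigned samples) as the
  denominator for MFO and MC, making `MC = MMD × MFO / 10` an exact
  identity and `Σ MC = assigned fraction`. MMD is the *mean* run
  duration (the field sometimes says "median" in the name while
  defining a mean; the definition wins here). Clustering is per
  subject; no cross-subject group templates are fitted.

## Feature selection

All three arms operate on internally z-scored predictors and are pure
functions of (table, seed).

* LASSO: L1 logistic path over 50 log-spaced penalties from the
  data-derived λ_max down 3 decades, 10-fold stratified CV of binomial
  deviance. `lasso_min` is the nonzero set at the deviance minimum,
  `lasso_1se` at the largest penalty within one standard error. The
  consensus uses `lasso_min` (the 1-SE set is typically too small to
  intersect meaningfully).
* Random forest: impurity importances from a 500-tree seeded forest;
  retained = importance above the mean importance, capped at the top
  10. The cap keeps the retained set in the single digits on
  signal-bearing tables and is deterministic.
* Boruta: implemented from the algorithm definition — per iteration,
  an independently shuffled shadow copy of every undecided feature is
  appended, a 100-tree forest fitted, and a feature scores a hit when
  it beats the best shadow importance; accumulated hits are tested
  against Binomial(trials, ½) one-sided in each direction with
  Bonferroni correction across the currently undecided features
  (α = 0.05), deciding confirmed/rejected; leftovers at 100 iterations
  are tentative and excluded from the consensus.
* Consensus = lasso_min ∩ rf_retained ∩ boruta_confirmed, emitted in
  forest-importance order; an empty intersection warns and returns an
  empty list.

## Modelling

70/30 stratified split (stratification prevents degenerate test sets at
cohort sizes near 50); per-feature standardisation fitted on the
training partition only. Five families are tuned by repeated stratified
10-fold CV (5 repeats by default) maximising mean AUC; each grid is
ordered simplest/most-regularised first so ties resolve conservatively.
The random-forest grid (trees {50, 100, 200} × min-split {10, 5, 2},
unlimited depth, fixed random_state 42) contains the reference
configuration of 50 trees with min_samples_split 10. The XGBoost grid
controls capacity through n_estimators {50, 200} × depth {2, 3, 4} ×
learning rate {0.05, 0.1, 0.3} rather than early stopping — an
equivalent regularisation control that keeps the grid search
deterministic and CV-uniform. SVM uses an RBF kernel with C/γ grids,
logistic regression an L2 C grid, the decision tree depth 2–8.

Evaluation: AUC from the probability ranking; Brier = mean squared
probability error; threshold metrics (default 0.5) from the confusion
matrix, with F1/PPV/NPV computed from their definitional formulas.
Bootstrap 95% CIs are percentile intervals over subject resamples;
single-class resamples are redrawn and counted. Calibration uses 10
equal-width bins: ECE is the bin-weighted mean absolute gap between
mean predicted probability and event rate, MCE the maximum gap (so
ECE ≤ MCE by construction); the bias-corrected reliability curve
refits on bootstrap resamples, evaluates on the original sample and
averages the curves (B = 200). Decision curves use the standard net
benefit `TP/n − (FP/n)·pt/(1−pt)` against treat-all and treat-none.
The "optimal" threshold maximises Youden's J over the midpoints of
gaps between consecutive distinct probabilities (ties take the lowest);
the deployed tool's published operating point, 48.83%, is the default
of the single-subject predictor. Sample-size planning follows the
events-per-variable rule `ceil(n_vars × EPV / (1 − incidence))`, with
the achieved ratio reported as events/variables to one decimal.

## Explanation

Shapley values are computed on the probability scale with an
interventional value function: v(S) is the mean predicted probability
over a background sample (default: the cohort, subsampled to 100 rows)
with the subject's values substituted on coalition S. With ≤ 12
features all 2^d coalitions are enumerated — the exact Shapley value —
via one batched prediction per subject; beyond 12, a seeded
permutation-sampling estimate is used. Both satisfy
`base + Σ contributions = model output` exactly (telescoping), which
the tests assert to 1e-9 on the probability scale. Cohort-level
rankings order features by mean absolute contribution. The
single-subject predictor validates the input against the training
schema (missing features are errors, extras are warned and ignored),
applies the stored scaler, and partitions contributions into
risk-increasing and risk-decreasing sets, echoing a clinical
disclaimer.

## Problem sizes

Library defaults target the acquisition protocol (180 s at 500 Hz, the
full 630-combination search). Validation runs use sizes chosen to keep
the suites comfortably reproducible on one core: cohort-level checks
simulate 80 subjects at 60 s / 250 Hz with a (2, 2, 2, 2) candidate
bank; duration-rank recovery uses the full 180 s at 500 Hz over 20
seeds; selection power/null checks use n = 300 tables over 20 seeds
(10 in the acceptance script); explanation checks use 150-subject
tables with 30-row backgrounds. All sizes are stated where used.

## Known limitations

* Backfitted absolute durations are compressed relative to planted
  means (see above); comparisons should be within-pipeline, as in the
  source literature.
* Published tables in this literature report MC, MMD and MFO with
  denominators that break the exact `MC = MMD × MFO / 10` identity by
  ~10%; this package keeps the identity exact, so absolute values are
  not directly comparable to such tables.
* The EDF writer emits classic EDF (16-bit, 1 s records, integer
  sampling rates); EDF+ annotations and BIDS layouts are out of scope.
* Boruta and forest importances inherit the biases of impurity-based
  importance (correlated-feature dilution); the consensus intersection
  mitigates but does not remove them.
* Clinical thresholds (48.83%) and the study's real-data performance
  are inputs from the source setting, not quantities this package can
  re-derive without the private cohort.
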