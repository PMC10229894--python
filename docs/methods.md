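# Methods

This note documents the models, numerical choices and limits of `dcx`:
what each stage computes, why the defaults are what they are, and what
passing the test suite does and does not demonstrate about real data.

## The synthetic cohort generator

**Purpose.** The imaging data of the emulated study design are not
publicly available, so the generator is the package's test bed: it
produces two-group cohorts in which the ground truth (which ROIs differ,
in which direction, and how behavior couples to the brain) is known
exactly.

**Model.** Each group has a target ROI-by-ROI innovation correlation
matrix built from a modular block structure: `rho_within` (default 0.3)
inside each of `n_modules` contiguous modules (default 6), `rho_between`
(default 0.1) across modules, unit diagonal. A planted effect at ROI *k*
adds a signed delta to that ROI's whole off-diagonal row and column,
clipped to ±0.95 — a node-level perturbation, chosen because degree
centrality is a node statistic; perturbing whole modules would confound
the planted "hub" change with community structure. Both matrices are then
repaired to positive definite by eigenvalue flooring at 1e-6 with
diagonal renormalization, iterated until the floor holds; this repair is
deterministic and order-independent. Subject time series follow a vector
AR(1), `x_t = φ x_{t−1} + ε_t` with `φ = 0.4` and `ε ~ N(0, Σ_group)`,
initialized from the stationary distribution. Because a common `φ`
scales the stationary covariance by `1/(1−φ²)` uniformly, the lag-0
correlation of the process equals the innovation correlation — the
planted deltas survive the temporal coloring exactly.

**Defaults as study conditions.** 22 subjects per group, 246 ROIs, 190
volumes at TR = 2 s with the first 10 dropped downstream, and seven
planted effects whose signs follow the reported discriminative regions
(the fusiform and left superior-frontal analogs increase, the middle
frontal, orbital, bilateral parahippocampal and right superior-frontal
analogs decrease). Only the signs are anchored; the delta magnitude
(default 0.3) is a free simulation parameter, since the source SVM
weights are not correlation effect sizes. `φ = 0.4` gives realistic
low-frequency autocorrelation for 2-s sampling.

**Voxel mode.** Each ROI's series is copied to the `voxels_per_roi`
(default 7) voxels of a contiguous-block parcellation on a small grid
(default 12×12×12, identity affine) with independent Gaussian noise
(SD 0.5). This exercises the full NIfTI/label-volume plumbing without
shipping a real atlas; it contains no anatomy, no spatial autocorrelation
beyond parcel identity, and no hemodynamics.

**Behavior.** Expertise-task scores are drawn per group at the target
means/SDs (0.80 ± 0.04 vs 0.53 ± 0.04); within the expertise group the
score is a linear function of the fusiform-analog ROI's DC plus noise,
calibrated so the population brain–behavior correlation is 0.5. Response
time (2.6 ± 0.4 s vs 3.7 ± 0.7 s) and the face-memory control score
(56.95 ± 5.23 vs 58.68 ± 5.31) are generated group-wise without brain
coupling, mirroring the null findings for those measures. Scores are
clipped to their natural domains ([0,1]; > 0), which is negligible at the
default SDs.

**What the generator does not emulate:** head motion, physiological
noise, scanner drift beyond what detrending/bandpass would remove,
spatial registration error, anatomical variability, non-Gaussian BOLD
statistics. Passing tests therefore shows the *algorithms* behave as
specified under a controlled generative model — not that the pipeline's
effect sizes or error rates transfer to real acquisitions.

## Temporal preprocessing

Stages operate on `(T, channels)` arrays and compose in the recorded
order: drop (default 10 volumes) → optional smoothing → confound
regression → linear detrend → bandpass. Nuisance regression precedes
filtering, matching the usual resting-state order; the order is exposed
in configuration and recorded in output metadata.

- **Friston-24**: blocks `[R_t, R_{t−1}, R_t², R_{t−1}²]`; the first row
  of each lagged block is 0 (a common convention where the pre-series
  motion state is unknown).
- **Confound regression**: OLS with an internal intercept; rank-deficient
  designs drop collinear columns with a warning (greedy rank-increasing
  keep, deterministic). Residuals are orthogonal to retained confounds to
  1e-8 relative.
- **Bandpass**: an ideal DFT mask — bins with `low ≤ f ≤ high` are kept,
  inclusive at both edges, and the 0 Hz bin is removed whenever
  `low > 0`. An ideal mask was chosen over an IIR filter because its bin
  behavior is exactly testable and it is idempotent (a projection);
  the trade-off is implicit periodic boundary handling, acceptable for
  detrended series.
- **Smoothing**: per-volume Gaussian with
  `σ = FWHM / (2√(2 ln 2))` converted to voxels; isotropic voxels only
  (resampling is out of scope); off by default because the synthetic
  cohorts carry no spatial structure worth smoothing.

## Degree centrality

Edges are strictly suprathreshold positive correlations (`r > 0.2`); the
default edge weight is the Fisher z of the retained correlation, read
off the stated processing order (threshold, then r-to-z, then sum);
binary counts and raw-`r` sums are provided for sensitivity analysis.
Correlations are clipped to |r| ≤ 1 − 1e-6 before `atanh` so duplicated
series give a large but finite weight. Normalization is division by the
whole-brain in-mask mean (the literal "divided by the mean" reading); a
z-scored map is deliberately not the default. The voxel-wise computation
processes row strips of the correlation matrix and reduces immediately;
partitioning only the rows makes the result exactly independent of the
strip size (each row's sum is computed in one pass). Zero-variance
voxels are removed from the mask with a warning; parcels with no in-mask
voxels are dropped, and the pipeline drops them consistently across
subjects.

## Feature selection and classification

- **Stage 1** — pooled-variance two-sample *t* per ROI, two-sided,
  uncorrected, retain p < 0.05. Degenerate features: zero pooled variance
  with equal means → p = 1 (never retained); with unequal means → p = 0
  (retained). If nothing passes, the single smallest-p feature is kept so
  every fold yields a model.
- **Stage 2** — contribution-guided RFE: for active set S with LOO
  accuracy acc(S), contribution(f) = acc(S) − acc(S∖{f}); all features
  with contribution ≤ 0 are removed together; if none qualify, the single
  smallest-contribution feature is removed (ties: larger column index
  first); if removing all would empty the set, the feature whose removal
  hurts most is kept. The loop stops at one feature. The chosen subset is
  the recorded set with maximal accuracy, ties toward the smaller set,
  then the earlier iteration. A classic smallest-|weight| RFE is
  available as `strategy="weight"`.
- **Classifier** — soft-margin linear SVM (hinge loss), C = 1.0 by
  default; features are standardized on each training fold (SVMs are
  scale-sensitive across ROIs and the source is silent on scaling).
  Expertise is coded +1, so positive weights mean higher DC in the
  expertise group.
- **Evaluation** — nested LOOCV is the scientific default: both selection
  stages re-run inside every outer fold, so the held-out subject never
  touches its own selection or standardization (instrumentation hooks let
  tests assert this). A `pooled` mode (selection once on all subjects,
  then LOOCV) is provided because single published region lists usually
  come from pooled selection; its output is explicitly labeled
  optimistically biased, and on null data it scores above the nested mode
  on average. The final descriptive region/weight table is a
  pooled-selection model refit on all subjects, labeled as such.
- **Metrics** — accuracy/sensitivity/specificity as percentages rounded
  half-up to 2 decimals; AUC by Mann–Whitney pair counting (ties 0.5) to
  4 decimals, which equals the trapezoidal area under the empirical ROC
  for tie-free scores.

A known behavior worth stating: with very strong planted effects the
inner LOO accuracy saturates at 1.0, every feature's contribution is
zero, and the smallest-set tie-break collapses the chosen subset to a
single ROI in every fold. Redundant truly-informative ROIs are then *not*
enumerated by the selection union — a property of this elimination rule,
not a defect; the weight-ranked strategy behaves similarly. Recovery of
the full planted set is reliable at moderate effect sizes.

Leave-one-out on a single uninformative feature is pessimistically
biased (mean accuracy below 0.5): each training fold's class balance
tilts against the held-out subject. Fold-wise selection offsets this in
the full pipeline, which calibrates at chance on null cohorts.

The LOOCV hot loop calls the low-level libsvm binding that backs
`SVC(kernel="linear")`; a test asserts exact weight/bias agreement with
the public estimator across random instances.

## Group statistics

Mann–Whitney U is exact by enumeration over all group assignments of the
pooled values (valid under ties) when the combined sample size is ≤ 12 —
the cutoff balances enumeration cost (C(12,6) = 924 assignments) against
the quality of the tie-corrected, continuity-corrected normal
approximation used above it. The two-sample t is pooled-variance by
default with a Welch option. Brain–behavior analysis computes per-ROI
Pearson correlations within the named group and applies
Benjamini–Hochberg FDR across ROIs separately per behavioral measure
(the most conservative defensible family at region level); correlation
is implemented at ROI level because the DC features are parcel averages.
Note that at n = 22 per group a true within-group correlation of 0.5
rarely survives an FDR family of 246 ROIs — the power analyses in the
tests use larger n for exactly this reason.

## Problem sizes used in tests

Unit tests run at small sizes (tens of ROIs/voxels, tens of volumes).
The calibration suites use the study-design sample size (22/group,
T = 180 post-drop) with 50 ROIs and 20 seeded replicates — large enough
for stable pass/fail counts while keeping the whole suite around a
minute. The acceptance script runs the full 246-ROI default once; at
that size the end-to-end analysis takes a few seconds.

## Known limitations

- The elimination loop is O(|S|²) LOO evaluations per outer fold;
  hundreds of post-filter features would be slow.
- The ideal bandpass assumes the series is effectively periodic after
  detrending; very strong residual trends would leak across bins.
- The generator's noise model is Gaussian and stationary; robustness to
  artifacts is untested by design.
- Voxel mode uses a synthetic contiguous-block atlas, not real anatomy.
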