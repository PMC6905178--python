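# Methods

This note documents the models, estimators and design choices behind
`eegssb`: what each stage assumes, which knobs matter, and what the
synthetic cohorts do and do not establish about real data.

## Problem setting

The pipeline targets a case-control study design: two groups of school-aged
children (one with a history of protein-energy malnutrition in the first
year of life, one of healthy matched controls), each with a short
eyes-closed resting EEG recorded on the 19 channels of the 10/20 system at
100 Hz. The scientific questions are (i) which cortical regions and
frequency bands differ between groups, and (ii) whether a sparse, stable,
age-adjusted classifier built on log source band power can separate the
groups out of sample.

## Spectral analysis

Recordings are cut into non-overlapping 2.56 s windows (256 samples at
100 Hz; a 61.44 s recording gives T = 24 windows, trailing samples
discarded). Each window is mean-removed and Fourier transformed with a
rectangular taper (a Hann option exists but is off by default: no taper is
the minimal assumption, and band-averaged log power is insensitive to the
choice at these bandwidths). Coefficients are scaled by `1/sqrt(fs*n)` so
the periodogram integrates to the window variance (Parseval). Only
harmonics k = 1..48 (0.39-18.75 Hz) are retained: this is the only
48-component grid the window length supports below 19 Hz.

The sensor cross-spectrum per bin is `S_v = (1/T) sum_k V_k V_k^H`,
Hermitian PSD by construction.

Band summaries use the seven IFCN broad bands (delta 1.5-3.9, low theta
4-5.4, high theta 5.8-7.4, low alpha 7.5-9.4, high alpha 9.5-12.5, low
beta 12.8-14.9, high beta 15-19.14 Hz). Published band edges are 0.1 Hz
roundings of the bin grid, so bin membership is decided with a 0.01 Hz
tolerance (delta therefore covers bins 4-10, whose top bin centre is
3.90625 Hz). Bins falling in the gaps between bands belong to no band and
are dropped, not merged. Log power uses the natural log throughout; any
other base is an affine rescaling absorbed by the classifier.

## Source estimation

The observation model per frequency bin is `v_k = L i_k + e_k` with a
shared lead field L (sensors x sources), circularly-symmetric complex
Gaussian sources with precision matrix Theta, and white sensor noise
`sigma_e^2 R` (R defaults to identity; the package accepts a measured R
but never estimates one). An L1 prior on the off-diagonal of Theta makes
the source partial coherences sparse.

Estimation is two-stage:

1. **Screening.** Each source j is scored by the evidence gain of the
   one-source model `v = L_j i_j + e` over the noise-only model, maximising
   the marginal likelihood over the scalar source variance in closed form
   (matrix determinant lemma + Sherman-Morrison), summed over bins and
   windows. The top `keep_fraction` (default 0.1) of sources is retained,
   always at least one.

2. **EM with a graphical-lasso M-step.** With the active set fixed, the
   E-step computes the posterior source cross-spectrum
   `S_post = T S_v T^H + (Sigma - T L Sigma)` with the Wiener transfer
   `T = Sigma L^H (L Sigma L^H + sigma_e^2 R)^-1`; the M-step solves the
   L1-penalised precision problem on `S_post`. Because the M-step maximises
   the expected complete-data penalised likelihood exactly, the penalised
   evidence is monotone non-decreasing across iterations (asserted in
   tests up to solver tolerance, 1e-7 relative).

Numerical choices:

- The glasso penalty inside EM is *relative*: the effective penalty is
  `lam * max |offdiag(S_post)|`, frozen at the first E-step. Freezing keeps
  the evidence monotone; the relative scale makes the fit exactly
  equivariant under rescaling the EEG (log powers shift by `2 log c`, which
  the tests verify).
- Complex problems are embedded in the real 2n x 2n isomorphism (each
  entry a 2x2 block) and solved with the standard real coordinate-descent
  graphical lasso, penalising |Re| + |Im| of each off-diagonal entry. This
  elementwise penalty is invariant under the complex-structure symmetry,
  so the unique solution retains the Hermitian block structure; it was
  preferred over a modulus (group) penalty because it reuses a well-tested
  solver unchanged and differs only in how the two parts of one complex
  entry share the budget.
- `lam = 0` returns the plain inverse; `lam >=` the largest off-diagonal
  returns the exact decoupled solution `diag(1/S_ii)` (the known glasso
  threshold property).
- `sigma_e^2` defaults to the smallest eigenvalue of the per-bin sensor
  cross-spectrum — appropriate in the intended regime of many more sources
  than sensors, where the smallest eigenvalue tracks the noise floor. In
  full-rank toy problems (e.g. an identity lead field) this overestimates
  the noise and the variance should be supplied. An EM update for
  `sigma_e^2` from the residual power exists (`update_sigma=True`) but is
  off by default; both conventions appear in the source-imaging
  literature, and fixing the noise is the more conservative default.
- An optional per-bin BIC selection over a penalty grid (`lam_grid`) is
  available; the default uses a single relative penalty because the BIC
  sweep multiplies the cost by the grid size.
- Inactive sources report the per-bin noise floor referred to source scale
  (`sigma_e^2 /` mean squared lead-field gain) rather than minus infinity,
  keeping the feature table finite.
- Convergence: relative evidence change below 1e-6, at most 50 iterations;
  non-convergence warns and returns the last iterate.

Region summaries average log power over the sources mapped to each region
(region order fixed by the map file).

## Stable sparse biomarker selection

Features are `x_ij = log s_ij`, the log source band power of subject i in
(region, band) j. Labels are coded Control = +1, PEM = -1 and fitted with
squared-error loss — the printed objective of the procedure this package
implements — not logistic deviance (a logistic option was considered and
rejected to keep fidelity to that objective).

The age-adjusted design contains, for each candidate feature, the feature
itself and its exact elementwise product with age, plus an unpenalised age
main effect:

    t_i = phi0 + x_i' phi + age_i (x_i' psi) + alpha age_i,
    d_j(age) = phi_j + age psi_j.

Base and interaction columns are standardised with training-split
statistics only; the age column enters raw (it is a nuisance covariate and
unpenalised, so its scale is irrelevant). If all ages are equal the
interaction block is exactly collinear with the base block and is dropped
with a warning. A feature's base (phi) and interaction (psi) terms are
selected and counted independently — with positive ages the two columns
are strongly correlated and the lasso may keep either twin.

**Step 1 (selection).** Five hundred times (default), the sample is split
stratified 70/30. On the training split:

1. the `indfeat` screen keeps features whose absolute two-sample t
   statistic exceeds the 90th percentile of the split's |t| distribution
   (at least 10 features always);
2. an elastic net is fitted on the age design, and the identity of the
   nonzero phi/psi terms is recorded.

Per-feature selection frequencies are the means of these indicators;
terms with frequency >= 0.5 (default) form the stable set, on which a
final model is refitted on the full sample with (gamma, lambda) by
cross-validation.

*Choice of the selection penalty.* The recording step uses a **fixed,
permutation-calibrated lasso penalty** per resample: the 0.9 quantile of
the permutation null of `max_j |z_j' y_perm| / n` (100 label permutations),
i.e. the smallest penalty at which no term would enter the path for a
label-permuted response. This was a genuinely open design point and the
most consequential one in the package. The alternative — tuning
(gamma, lambda) for prediction inside each resample by cross-validation —
was implemented (it remains available as `selection="cv"`) and found to
destroy the calibration of selection frequencies at desk scale: a
prediction-optimal penalty admits moderately correlated nuisance features
(any fixed cohort of ~120 subjects and ~350 features contains chance
correlates with |t| near 3.4, and features correlated through the global
power factor genuinely improve within-cohort prediction as nuisance
controls), so those features are "selected" in well over half the
resamples and pure-null cohorts fail to return empty stable sets. Holding
the penalty at the family-wise false-entry level across resamples is the
standard stability-selection prescription (fix the regularisation region;
let the resampling do the testing), keeps the selection event comparable
between resamples, and makes the null calibration exact by construction.
At the original study's scale (hundreds of thousands of features, where
any individual null is rarely even screened) the two rules converge;
at desk scale only the fixed rule yields interpretable frequencies. The
permutation calibration also mirrors how the group-contrast maps are
thresholded. Prediction-oriented cross-validation is retained exactly
where prediction is the goal: the final stable-set refit and every Step 2
evaluation refit.

**Step 2 (evaluation).** With the stable set frozen, an independent set of
resampled 70/30 splits refits the coefficients on each training split
(restricted to the stable terms, CV for the penalty) and scores the
held-out 30%. Scoring held-out subjects — rather than the training split —
is the only reading consistent with out-of-sample evaluation, and is what
the package does. Per resample the full AUC and the partial AUCs below
false-positive rates 0.1 and 0.2 are computed (trapezoid, linear
interpolation at the cutoff); partial AUCs are standardised after McClish,
`spAUC = (1 + (pAUC - c^2/2)/(c - c^2/2))/2`, and below-chance values are
clipped to chance with a warning (the transform is undefined there).
Resampled values are summarised by Gaussian kernel densities (Silverman
bandwidth, reflected at the [0, 1] boundary) and their medians; the
held-out subject scores of the median-AUC resample are exported for box
plots. The number of evaluation resamples defaults to the Step 1 count.

Sign convention: with Control = +1, a positive d_j(age) means higher power
in feature j drives the score toward the control group. Exponentiating the
score (net of the intercept and age main effect) expresses the classifier
as a product of band powers raised to age-dependent exponents — a
data-driven generalisation of classical band power ratios (alpha/theta is
the special case d_alpha = 1, d_theta = -1).

## Group contrasts and demographics

The contrast map reports pooled-variance two-sample t statistics
(PEM minus Control) per (region, band), thresholded at the (1 - alpha)
quantile of the max-|t| distribution over label permutations (global
max-statistic across the whole map: strong family-wise control; a per-band
threshold was considered and rejected as less conservative). Negative
flags mean lower activity in the PEM group.

Demographic-table helpers use the Welch form of the two-sample t from
summary statistics (the Welch form reproduces the reference female-age
value; a pooled option exists) and the Pearson chi-square for 2x2 tables
without continuity correction (which reproduces both reference values
exactly).

## Synthetic cohorts

Each source carries one damped-oscillator AR(2) process per broad band
(poles at `rho e^{+-i theta}`, centre frequency = band midpoint,
half-bandwidth 0.1 x band width — this keeps >90% of an oscillator's power
inside its band), scaled to a target log band power. Because group effects
scale oscillator amplitude multiplicatively, the group difference in mean
log band power equals the specified shift exactly in expectation,
independent of oscillator details. Sensor EEG is exactly `L @ sources`
plus white noise; the default lead field is a seeded Gaussian matrix with
unit-norm columns shared by all subjects (one average template matrix for
the whole cohort; realistic head modelling is out of scope), with an
identity option for controlled tests.

Default study conditions: 46 PEM + 62 control subjects, ages uniform on
[5, 11] years (both groups drawn from the same distribution, i.e.
age-matched in distribution), 19 sensors, 61.44 s at 100 Hz. The default
effect cohort carries a -0.5 log-power low-alpha deficit in one region
with an age slope of -0.1 per year centred at age 8 (the cohort midpoint;
centring makes the baseline shift and the slope separately identifiable) —
a stand-in for a posterior-cortex alpha deficit that grows with age.
The source grid defaults to 50 sources / 50 regions: classifier
experiments operate at region level, and the full cortical-grid resolution
of the original analysis is out of desk-scale reach by design (grid size
is configurable).

Unstated-by-necessity amplitude choices, fixed once: nominal band powers
follow a 1/f-like profile with an alpha prominence (eyes-closed children);
between-subject variability of log band power is one global scale deviate
(SD 0.25) plus one deviate per (region, band) shared by the region's
sources (SD 0.4) — within the range reported for absolute log band power
in school-aged children, if anything optimistic; sensor noise SD defaults
to 1 in the source amplitude units. Demographic covariates (sex,
handedness) follow the study's proportions and carry no EEG effect.

What the generator does *not* emulate: real head geometry and volume
conduction structure, artifacts (ocular, muscle, somnolence), non-Gaussian
graphoelements, sex effects, within-band spectral peaks that shift with
age. Passing tests therefore establish the statistical machinery
(calibration of selection frequencies, out-of-sample ROC behaviour,
contrast thresholds) under the assumed generative structure — not
robustness to real-world EEG artifacts.

An important honest consequence of the chosen variability level: a -0.5
log-power shift against a between-subject SD of ~0.5 is an effect of
d ≈ 1.0, whose single-feature population AUC is about
`Phi(d/sqrt(2)) ≈ 0.76`. Realised cohorts of 120 subjects scatter around
this value, so the median held-out AUC of the recovered classifier sits
near 0.73-0.79 and falls below 0.75 in roughly half of seeded replicates,
even when the seeded feature is selected cleanly. The selection
calibration results are unaffected.

## Problem sizes used by the test suite and acceptance script

Calibration experiments run 20 seeded cohorts of 60+60 subjects with
50 regions x 7 bands, 100 selection resamples and 100 evaluation
resamples; source-estimator checks run 2-12 sources, 3-19 sensors,
6-48 bins and 100-200 windows. These sizes were chosen so a complete run
is a coffee-break computation on a laptop while keeping every Monte-Carlo
check at 3-sigma resolution or better.

## Known limitations

- The screening stage is a univariate evidence screen; it implements the
  stated model class, not a line-by-line port of any particular published
  solver, and its hyperparameters (keep fraction) are user-set rather than
  evidence-optimised.
- Connectivity (partial coherence) outputs are estimated but not used as
  classifier features.
- The elastic-net loss is squared error on coded labels; probabilities are
  not calibrated and scores are only rankings.
- EDF export is not implemented (no writer backend available); delimited
  text is the interchange format, EDF reading is optional via mne.
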