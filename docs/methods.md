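# Methods

This note documents the models, rules and numerical choices behind
`strikekin`, and what its synthetic generators do and do not emulate.

## Camera model and 3D reconstruction

Cameras are modelled by the standard 11-parameter direct linear
transformation (DLT).  No lens-distortion terms are included: the workflow
this reimplements uses the same 11-coefficient model, and typical macro
setups filming a ~10 cm working volume are dominated by tracking noise, not
distortion.  Calibration solves the linearized projection equations in least
squares; the point set must contain at least six non-coplanar points, and
rank deficiency (coplanar or collinear clouds) is detected from the singular
values of the centered point cloud.  Stereo reconstruction solves the 4×3
two-camera system per landmark and frame; landmarks missing in either view
(including points suppressed by the tracking-confidence cutoff, default 0.6)
yield missing 3D values, never zeros, since zero is a valid pixel
coordinate.  Per-trial mean and maximum reprojection errors are recorded as
quality diagnostics.  World units are cm, time s, angles degrees throughout.

## Landmarks, angles and the 16 kinematic variables

Ten landmarks are tracked: left foreleg (1 thorax/coxa joint, 2 trochanter,
3 femur–tibia joint, 4 tibia tip), 5 mesocoxal joint, 6 prey, 7 left eye,
8–10 the right-leg homologs of 2–4.  Joint angles are measured on the left
leg: the coxa angle at point 1 between the metazona axis (1→5) and the coxa
(1→2), the trochanter/femur angle at point 2 between 2→1 and 2→3, and the
tibia angle at point 3 between 3→2 and 3→4.  These reference vectors are a
documented choice (the landmark scheme does not force them); they are what
the rigid-chain geometry makes natural and they are rotation- and
translation-invariant by construction.

Event rules, all thresholds configurable in `PipelineConfig`:

* **strike start** — the earliest frame at which any foreleg landmark's
  speed exceeds its baseline noise floor (mean + 3 SD over the first 20
  frames; if the baseline is silent, 5% of the trial maximum).  "The moment
  the forelegs move" is not otherwise operationalizable.
* **capture** — the first frame the prey lies inside the triangle spanned by
  the two tibia tips and the midpoint of the trochanters, within a
  plane-distance tolerance of 10% of mean femur length.  A prey that never
  enters raises a typed error and the attempt is excluded (and logged),
  never silently dropped.
* **approach start** — standardized coxa angle reaches 5% of the peak coxa
  angle, where the peak coxa angle is 99% of the maximum measured
  standardized angle and "standardized" means the smoothed series minus its
  window minimum.
* **approach end / sweep start** — the femur angular velocity first reaches
  10% of its maximum after approach start.  Approach + sweep time equals the
  capture-to-approach-start duration exactly, by construction.

The femur and tibia open and then close, so their peak angles are read at
the highest local angular peak before capture (`scipy.signal.find_peaks`
with a small prominence guard); a monotone series raises a no-peak error.
Angular velocity maxima are the extrema of the smoothed-angle derivative;
the tibia, which flexes to secure prey, reports the absolute value of its
most negative velocity.  Segment linear velocities differentiate the
cumulative 3D path of each segment's distal joint (a documented choice; the
segment midpoint is the plausible alternative).  Body motion tracks the
midpoint of points 1 and 5.  Lateral displacements are maxima of the
smoothed 3D distances between homologous left/right joints.  The
predator–prey angle is measured in full 3D between the anterior body axis
(5→1) and the eye-to-prey vector; distance is eye-to-prey at strike start.

**Starting coxa angle.**  The reported variable is the *raw* smoothed coxa
angle at strike start, not the standardized one: under standardization a
monotonically abducting coxa always starts at zero, which cannot express the
inter-species posture differences (e.g. ~87° in flower mimics vs ~29° in
basigrade hunters) the variable exists to capture, nor drive the 50°
hunting-style cut.  A config switch (`coxa_start_standardized`) restores the
standardized alternative.

## Smoothing

All series are smoothed with an order-10 least-squares polynomial.  Two
modes exist:

* `global` — a single polynomial over the analysis window (the strike
  padded by 10 frames), with the derivative evaluated from the fitted
  coefficients.  This is `fit_poly_smooth`.
* `windowed` (default) — the same order-10 least-squares fit applied in a
  13-frame sliding window (Savitzky–Golay), derivative again from the local
  coefficients.

The windowed mode exists because a single degree-10 polynomial spanning a
50–90-frame window mathematically cannot track a tibia flexion lasting
~10–20 ms: measured on noiseless profiles, the global fit biases peak
angular velocities by 3–100% depending on the timeline, while the 13-frame
windowed fit keeps every extracted variable within 1.4% / 0.1° / 1 ms of
generator truth across the full sweep of realistic strikes.  The price is
weaker noise averaging (a high-order fit in a short window is close to
interpolation); with noisy tracking, a longer window (e.g. 17–21 frames)
trades recovery bias for noise suppression and can be set in the config.
Interior missing frames are linearly interpolated before fitting, as
high-order fits are unstable on gappy data.

Cumulative path lengths (used for linear velocities and body displacement)
inflate under coordinate noise (a random-walk bias); this is inherent to
path-based displacement definitions and is not corrected.

## Synthetic strike generator

`make_strike` drives a rigid chain with raised-cosine (smoothstep) angle
profiles, chosen so that derivatives exist everywhere and the analytic
maxima are closed-form: a ramp of amplitude Δ over duration D has peak rate
Δπ/2D at its midpoint.  The timeline is laid out so the *operational* phase
definitions hold analytically: the coxa rises from its start to its peak
angle between strike onset and approach end; the femur's fast opening is
placed so its 10%-of-max velocity crossing lands exactly `approach_duration`
after the coxa's 5% crossing; the tibia opens through the approach and
flexes during the sweep, closing before capture.  The lateral spread
half-angle is calibrated by root finding so the maximum tibia-tip separation
equals the requested value.  The prey holds position, then darts linearly
into the centroid of the final foreleg triangle; its motion onset is delayed
adaptively until the first containment frame (under the same geometric rule
the detector uses) is the nominal capture frame, preventing accidental early
crossings of the sweeping triangle.  Path-dependent truths (linear velocity
maxima, lateral displacement maxima) are evaluated on the continuous model
at 8× frame resolution.

What the generator does *not* emulate: tracking-confidence dropouts and
identity swaps, lens distortion, out-of-plane leg rotation (each leg moves
in a tilting plane), prey evasion, and failed strikes.  Passing the recovery
suite therefore demonstrates correctness of the measurement chain, not
robustness to every pathology of real footage.

The study-cohort generator (`strikekin.cohort`) works at the
kinematic-table level: 10 species in three families and four camouflage
strategies, 48 individuals, five attempts each (239 total), with species
means taken from the published values where printed and realistic fill-ins
elsewhere, plus multiplicative individual and trial variation (additive for
angles, CVs of 6% and 9%).  Its companion phylogeny groups species by family
on a fixed ultrametric unit-height tree.  It reproduces the study's design
quantities (144 selected attempts, species-mean starting angles, the
two-anterograde-species split); its PCA spectrum is not expected to match
the published proportions, which depend on the real trials' correlation
structure.

## Comparative statistics

* **Selection.**  "Three fastest per individual based on tibia and femur
  angular velocities" is operationalized as the top three by the sum of
  within-individual z-scores of the two velocity maxima — symmetric in the
  two criteria — with ties broken by femur velocity, then trial id.
* **PCA** is computed on the correlation matrix (z-scored variables), since
  the 16 variables mix cm, s and deg/s.  Proportions of variance are
  eigenvalues over their sum (exactly 1 by the unit trace); component signs
  are oriented so each component's largest-magnitude loading is positive.
* **Broken stick**: component k of p is significant while its observed
  proportion exceeds `b_k = (1/p) Σ_{i=k..p} 1/i`; counting stops at the
  first failure.
* **PGLMM**: Gaussian mixed model with a phylogenetic species effect
  (covariance σ²_phylo · Σ, where Σ is the shared-branch-length matrix of
  the unit-height tree) and an i.i.d. species effect.  Fitted by direct
  profile optimization of the two variance ratios under REML (L-BFGS-B
  multistart with a Nelder–Mead polish; the profiled surface is flat near
  the boundaries).  The ML log-likelihood at the REML ratios feeds
  AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects plus
  the three variance components.  This engine is deterministic and
  desk-scale; it replaces the original study's MCMC sampler and estimates
  the same quantities, so its lambdas and p-values are analogs, not
  replicas.  Boundary estimates (a variance at zero) are reported, not
  errors.
* **Lambda** is reported in variance-share form,
  σ²_phylo/(σ²_phylo+σ²_species+σ²_resid).  Continuous morphology
  predictors enter as species means plus within-species deviations
  (within-species centering).  Fixed-effect p-values are Wald; pairwise
  camouflage contrasts are differences of estimated marginal means
  (numeric covariates at their means, other factors averaged over levels),
  unadjusted by default with a studentized-range (Tukey) option.
* **Hunting style**: anterograde above a 50° starting coxa angle, basigrade
  at or below it (the boundary value is assigned basigrade).

**Known limitation — lambda at few species.**  With 10 species the REML
point estimate of the phylo/species variance split is extremely noisy: a
substantial fraction of replicates sits on a boundary (λ̂ = 0 or 1).  At
moderate signal the estimator's mean is within ~0.05 of the generative
variance share (the recovery tests run there), but at strong signal the
zero-boundary mass biases the mean downward by ~0.1–0.2.  Single-dataset
lambdas at this species count should be read as order-of-magnitude
statements, which is also why cross-engine (REML vs MCMC) lambda agreement
is only approximate.

## Simulation-based trait model

`simulate_traits` draws the response as fixed effects + a phylogenetic
species effect with covariance σ²_phylo·Σ(λ) — Σ(λ) being the tree
covariance with off-diagonals multiplied by λ (the Pagel transform) — plus
an i.i.d. species effect and residual noise.  Because
σ²_phylo·Σ(λ) = λσ²_phylo·Σ + (1−λ)σ²_phylo·I, the implied variance-share
estimand of the fitted model is λ·σ²_phylo/(σ²_phylo+σ²_species+σ²_resid);
recovery tests compare estimates to that share.

## Problem sizes and tolerances

The test suite and the acceptance script use: 50-strike recovery sweeps
spanning starting coxa angles 20–90°, femur angular velocities
4000–9500 °/s, tibia 7500–14,500 °/s and lunges 0.3–1.4 cm, at 1000 fps
(tolerances: angles ±1°, times ±2 ms, velocities and linear quantities
±2%); DLT noiseless round trips below 1e-6 cm; lambda recovery over 200
replicated 10-species × 5-individual simulations (mean within ±0.1 of the
implied share); exact reduction to OLS and agreement with an independent
two-level mixed-model fit at the variance boundaries; Monte-Carlo
covariance checks with ≥ 2000 replicates.  The full suite runs in about a
minute on one CPU; the acceptance script in about half a minute.
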