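# Methods note

This note records the quantitative model behind `microexplore`, the
parameters and their defaults, what the synthetic cohort generator does and
does not emulate, and the numerical choices that affect results.

## 1. Data model

Input is markerless pose-estimation output for the base of a rope handle:
per-frame image coordinates \((x_t, y_t)\) in **pixels**, origin at the
top-left of the camera view, sampled at **30 fps**. Files use the de-facto
three-row-header CSV layout (`scorer` / `bodyparts` / `coords`, with
`x`/`y`/`likelihood` per body part); an HDF5 sibling with the same schema
is supported, CSV being canonical. Frames where the handle is occluded are
NaN coordinates with likelihood below 0.5; the time base is never
compacted or interpolated, and no likelihood filtering is applied unless
the caller opts in (`PoseTrack.mask_low_likelihood`).

Every analysed trial is clipped to its **first 20 s (600 frames)** so all
trials contribute equal data; trials shorter than the clip are rejected
(`InsufficientDataError`) rather than padded.

**Assumptions.** A single fixed camera, so one pixel-per-cm scale applies
to both axes; the handle base is a valid proxy for where the infant acts;
missingness from occlusion is ignorable for trial-level summaries.

## 2. Imitative baseline

The anchor \((x_0, y_0)\) is the **frame-weighted pooled mean** of handle
coordinates inside segments hand-labelled as imitative ("straight back")
pulls, pooled over all contributing infants: every labelled frame counts
once, so a 3 s segment contributes three times the weight of a 1 s
segment. NaN frames inside segments are skipped. Estimation fails loudly
(`AnchorEstimationError`) if no valid frame exists.

The default pixel scale is **458.29 px / 35.25 cm ≈ 13.0011 px/cm**; the
independent vertical pair 347.79 px / 26.75 cm gives the same ratio to
three decimals, which is the internal consistency check for the
single-scale assumption. `px_to_cm` accepts an override for other rigs.

## 3. Exploration metrics

With anchor \((x_0, y_0)\), per frame:

- deviations \(d_x = |x - x_0|\), \(d_y = |y - y_0|\) (px or cm);
- difference score \(d_x - d_y\) (positive = exploration is more
  horizontal than the demonstrated straight-back pull);
- imitative similarity \(-(d_x + d_y)\) (0 only at the anchor, more
  negative = further from imitation).

Two variability timescales, both sample SDs (**ddof = 1**), averaged over
x and y:

- **per-second**: SDs within each non-overlapping 1 s (30-frame) window,
  then the per-window x/y mean — movement *within* an attempt;
- **overall**: SDs about the trial-global means — breadth of locations
  tested *across* attempts.

A dwell-and-hop mover scores low on the first and high on the second; the
dissociation is the point of having both. Windows with fewer than two
non-missing frames give NaN; x and y use a combined missingness mask so
both SDs are computed over the same frames. Both measures are
**square-root transformed** before modelling to reduce right skew, as are
trying time and maximum force.

Per-frame scores are thinned to **1 Hz** before mixed modelling (20
records per 20 s clip) to avoid pretending 600 near-duplicate frames are
independent. The default rule keeps the final frame of each window; a
window-mean rule is available (the sampling rule is a design choice the
measures do not depend on strongly).

## 4. Inferential layer

- **t-tests**: one-sample (deviation against 0 = imitation) and paired
  (dev_x vs dev_y), via scipy.
- **Linear mixed models**: random intercept per participant (statsmodels
  `MixedLM`, REML), fixed effects condition (treatment-coded, *Easy*
  demonstration as reference), trial number, time within trial, their
  interaction, and trial-length / fine-motor covariates as appropriate per
  response. Rows with missing values are listwise-deleted and the count is
  recorded in the result's notes.
- **Percentage-bend correlation** (β = 0.2), implemented directly:
  median-centre each variable; let W be the sorted absolute deviations,
  \(m = \lfloor (1-β)n + 0.5 \rfloor\), bend scale \(ω = W_{(m)}\); scores
  are the centred values divided by ω, clamped to \([-1, +1]\); correlate
  the scores; test with \(T = ρ\sqrt{(n-2)/(1-ρ^2)}\) on n − 2 df. ω = 0
  (over 80% ties) raises `DegenerateDataError` rather than returning a
  number.
- **Pearson correlation** for the validity check against human-coded
  unproductive-movement intervals.
- **ICC** from two-way ANOVA mean squares, consistency
  \((MS_R - MS_E)/(MS_R + (k-1)MS_E)\) by default, absolute-agreement
  variant available. The appropriate model for a given rating design is
  the caller's choice; both are exposed, neither privileged.

All results are returned as a uniform `StatResult` (method, estimate, SE,
statistic, df, p, n, term, notes) and collected into one tidy table per
run with the number of tests reported alongside, so the multiplicity of
the report is visible.

## 5. Synthetic cohort generator

The generator emulates the *statistical structure* needed to exercise the
pipeline, not infant biomechanics:

- **Bout process.** Successive bout targets ~ 2D normal centred on the
  anchor with SD `sigma_explore_base + sigma_explore_trial_slope·(trial−1)`
  (150 px + 20 px/trial); dwell per bout ~ Exponential with mean
  `dwell_mean_base + dwell_time_slope·elapsed` (2.0 s + 0.05 s/s); frames
  within a bout are target + isotropic N(0, 10 px) jitter; coordinates
  clipped at 0 (image frame).
- **Occlusion.** Each frame independently missing with probability 0.02:
  NaN coordinates, likelihood drawn below 0.5; visible frames above 0.5.
- **Imitative engagement.** With probability 78/96 a participant's first
  bout of trial 1 sits exactly on the anchor; those frames form the
  labelled imitative segments. This is what makes sub-pixel anchor
  recovery testable.
- **Design.** Default 96 participants, round-robin over Easy / Hard /
  Impossible; 3 trials each; trial lengths 20 + Exp(18) s capped at 120 s;
  fine-motor score ~ Binomial(24, 0.75).
- **Performance measures** (max force, trying time, negative affect,
  help seeking, recovery hints) are drawn through a **Gaussian copula**
  tied to each participant's trial-averaged overall variability via its
  empirical normal scores, with planted correlations
  {+0.22, −0.27, +0.13, +0.11, −0.37} and an 80% participant-level
  variance share across trials, then mapped through skewed/discrete
  marginals. Trial-averaging and the non-Gaussian marginals attenuate the
  recovered percentage-bend correlations by roughly 0.05, which is why
  recovery is asserted within ±0.10 of the plant, not tighter.
- Human-coded **unproductive-interval** counts are independent integers
  0–4 unless a validation association is planted explicitly.

Not emulated: arm kinematics, force dynamics, rater noise structure,
dropout/fussing-out, camera distortion. Reproducibility is bit-for-bit:
every trial has its own `SeedSequence([seed, participant, trial])` stream,
so cohorts are stable under reordering and identical seeds give
byte-identical files.

## 6. Numerical choices

- **Exact zeros.** `np.std` of a constant series returns ~1e−13, not 0;
  the package's sample-SD helper returns exactly 0.0 when max == min, so
  the degenerate no-dispersion limit yields *exact* zeros for every
  metric.
- **Round-trip floats.** CSVs are written at shortest round-trip precision
  and read with `float_precision="round_trip"`, making
  write → read bit-exact (pandas' default float parser is not).
- **Quantile index convention.** \(m = \lfloor (1-β)n + 0.5 \rfloor\) is
  used for the bend scale. Some libraries use \(m = \lfloor (1-β)n
  \rfloor\) (truncation); for β = 0.2 the two differ whenever
  n ≡ 1 or 2 (mod 5), changing estimates by up to ~0.1 at small n. The
  rounding convention here follows the published algorithm; tests compare
  against an external implementation only at sample sizes where the
  conventions coincide, and against an independent in-suite oracle at all
  sizes.
- **Optimizer fallback.** `MixedLM` with the default L-BFGS can raise a
  singular-matrix error on well-posed cohorts; fitting tries Powell, then
  conjugate-gradient, then Nelder–Mead, which agree to ~1e−7 where all
  converge. Singular random-effects covariances are reported in the
  result's notes, not hidden.
- **Degrees of freedom.** Mixed-model Wald tests use the residual
  approximation df = n_obs − n_fixed; statsmodels does not provide
  Satterthwaite df for `MixedLM`. At the default sizes (≥ 5,000
  observations, 96 groups) the approximation is immaterial; at small n it
  is anticonservative, and the method name in the output table flags it.
- **Outlier handling** defaults to |z| > 3 on the per-participant
  deviation summaries, with every exclusion logged in the run's attrition
  table and a `none` rule available. The z-score rule is a conventional
  stand-in, not a claim about the right rule for infant data.
- **Window/tie handling.** 1 s windows are non-overlapping and aligned to
  frame 0; a trailing partial window is kept for variability (NaN if < 2
  frames) but the 1 Hz thinning emits only complete windows.

## 7. Problem sizes exercised

Unit and property tests run on 2–900-frame fixtures and 12-participant
cohorts (seconds). The acceptance suite runs a 20-seed recovery study of
full default cohorts — 96 infants × 3 trials × 30 fps, anchor estimation
through mixed models and robust correlations — in ≈ 40 s, and the
end-to-end pipeline on 4-participant cohorts for byte-level determinism
checks.
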