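# microexplore

Trajectory-based quantification of **exploratory vs imitative problem-solving
in infants**, from markerless pose-estimation output.

## The problem

When an 18-month-old watches an adult solve a rope-pulling task and then
tries it herself, she rarely either copies the model exactly or does
something entirely different. Instead she *micro-explores*: she varies the
location, angle and force of her pulls around the demonstrated solution.
Hand-coding cannot resolve these small parametric variations, but markerless
pose estimation can — it yields the rope handle's image coordinates
(pixels, origin at the top-left of the camera view) 30 times per second.

`microexplore` turns those per-frame coordinates into interpretable
measures of exploration and runs the inferential layer over them:

- **Imitative anchor** — the pooled mean handle position
  \((x_0, y_0)\) during pulls judged imitative ("straight back"), estimated
  from labelled segments across all contributing infants. It is the zero
  point of exploration, and its printed pixel/cm pairs fix the camera's
  pixel-per-cm scale.
- **Deviation and similarity** — per frame,
  \(d_x(t) = |x(t) - x_0|\), \(d_y(t) = |y(t) - y_0|\); the
  *difference score* \(d_x - d_y\) (positive = more horizontal exploration)
  and the *imitative similarity score* \(-(d_x + d_y)\)
  (0 = perfect imitation; more negative = more exploration).
- **Spatial variability at two timescales** —
  *per-second*: mean of the sample SDs of x and y within each 1 s window
  (local, real-time exploration); *overall*: the same SDs about the
  trial-global means (breadth of locations tested). An infant who dwells on
  one spot each second but hops between distant spots across a trial scores
  low on the first and high on the second — the two measures deliberately
  dissociate. Both are square-root transformed for modelling.
- **Inference** — one-sample and paired *t*-tests of deviation against
  imitation; random-intercept linear mixed models of each measure on
  condition (treatment-coded, Easy demonstration as baseline), trial
  number, time within trial, their interaction, and trial-length / motor
  covariates; **20% percentage-bend correlations**
  \(\rho_{pb}\) (median-centred, bend-scaled, clamped to \([-1,1]\)) linking
  performance measures (maximum pulling force, trying time, negative
  affect, help-seeking, recovery-trial hints) to exploration; Pearson
  validity checks against human-coded unproductive movement; two-way ICCs
  for rater reliability.
- **A bout-structured synthetic cohort generator** — dwell-and-hop
  trajectories with condition/trial/time-dependent dispersion and dwell,
  occlusion, and performance measures tied to overall variability through a
  Gaussian copula with known planted correlations, so the entire pipeline
  is testable end to end without any recorded infant data.

## Worked example

`examples/04_robust_correlation.py` shows why the robust correlation is the
workhorse for skewed performance measures:

```text
clean fixture:  rho_pb = 0.913 (p = 1.9e-12),  r = 0.948
with outlier:   rho_pb = 0.812,  r = -0.080
shift: bend 0.101, Pearson 1.028
```

One planted 100-SD outlier in 30 points moves the percentage-bend estimate
by 0.10 while the Pearson correlation collapses from 0.95 to −0.08.

`examples/03_variability_timescales.py` shows the timescale dissociation on
a simulated trial (2 s dwells, 150 px bout dispersion, 10 px jitter):

```text
mean per-second variability:   33.5 px
overall variability:          118.5 px
dissociation (local < global): True
```

Locally the handle barely moves (the infant persists within an attempt);
globally the tested locations are spread widely (the infant explores across
attempts).

The other examples cover pose-file I/O and clipping (`01`), anchor
estimation and deviation scoring (`02`), and a full simulated-cohort run
(`05`). A thin CLI wraps the same pipeline:

```bash
microexplore simulate --seed 1 --out cohort/
microexplore run --input cohort/ --seed 1 --out report/
```

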