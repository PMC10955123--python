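# Methods

`ecctrain` reimplements, as a tested pipeline over synthetic data, the
analysis chain of a randomized-controlled eccentric-training study of the
shoulder external rotators: isokinetic dynamometer signal processing,
passive-flexibility modelling, curve-level statistical parametric mapping
(SPM), cohort statistics, and muscle-DTI fascicle metrics. This note
documents the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic generators do and do not emulate.

## Dynamometer preprocessing (`isokin`)

Raw trials are series of time, joint angle (deg; 0 = lever perpendicular
to the body, positive = external rotation), torque (Nm) and angular
velocity (deg/s) sampled at 200 Hz.

- **Filtering.** Fifth-order Butterworth low-pass at 6 Hz, applied
  forward-backward (`scipy.signal.filtfilt`), so the net phase lag is zero
  and the effective attenuation is the squared magnitude response. The
  series must exceed the filter's padding length (3×(order+1) samples);
  shorter input raises an error naming the minimum.
- **Repetition segmentation.** Movements are maximal runs of constant
  velocity sign; samples at exactly zero velocity inherit the preceding
  sign so a grazing touch of v = 0 does not split a movement. Runs shorter
  than 0.1 s are treated as chatter and dropped. Positive velocity maps to
  "external". Indexing is 0-based with half-open ranges throughout.
- **Isokinetic phase.** The longest contiguous run with |v| within ±10% of
  the commanded speed. The tolerance is a configurable design choice (the
  protocol names none); the acceleration and deceleration ramps fall
  outside the band by construction.
- **Normalization and resampling.** Torque is divided by body mass
  (gravity correction is assumed already applied by the device) and
  linearly interpolated in angle onto 101 equally spaced nodes between the
  phase's angle extremes (0–100 %ROM). Duplicate angles are averaged
  before interpolation; endpoints are preserved exactly. Linear
  interpolation is exact on affine torque-angle data and shape-preserving
  on the smooth curves the generator produces.
- **Strength summaries.** Peak = max and mean = arithmetic sample mean over
  the isokinetic interval. Per subject, the default aggregation is the best
  repetition's peak and the mean of repetition means; both rules are
  configurable because the underlying convention (best-of-three vs
  mean-of-three) is not fixed by the protocol.

## Passive flexibility (`flex`)

Passive stretches at 10 deg/s are averaged over repeated trials
(resampled to the intersection of their angle supports) and fitted with the
three-parameter exponential

    T(theta) = a * exp(b * theta) + c

by least squares (Levenberg–Marquardt, parameter tolerance 1e-12, flagged
if non-converged). Initialization is deterministic: b from a log-linear
regression of the positive first differences dT/dtheta, then a linear solve
for (a, c). Near-linear data (|b|·span < 1e-3) is flagged degenerate rather
than silently reported. The alternative form a·(exp(b(theta−theta0))−1) is
available behind the `efunction_form` concept but the additive-offset form
is the default.

Range of motion is the inversion of the fit at a torque threshold:
ROM = min(ln((threshold − c)/a)/b, cap). Maximal ROM uses the 9 Nm test
criterion with caps of 100 deg (internal) / 140 deg (external rotation);
submaximal ROM uses a configurable lower threshold, default 4.5 Nm — half
the maximal criterion, explicitly a stand-in since the defining value lives
outside the study protocol. When the fitted asymptote c meets or exceeds
the threshold the cap is returned with a warning. Active ROM is the mean
extreme angle over stretch cycles, delimited by velocity-sign reversals.

## Curve-level SPM (`spmfield`)

At each of the Q = 101 nodes, a 2×2 mixed (split-plot) ANOVA — group
between subjects, time (pre/post) within, subject as random block — yields
F fields for group, time and group×time, each with df = (1, N−2). With two
within levels the decomposition reduces to two orthogonal strata: subject
means carry the group effect, subject pre-post differences carry time and
interaction; sphericity is automatic. For unequal group sizes the effects
involving time use unweighted cell-mean (Type III) contrasts, the
convention of the mixed-GLM reports this pipeline mirrors; with balanced
groups this equals the classic sums-of-squares decomposition (and the
pingouin cross-check in the tests).

Familywise inference over the curve uses 1D random field theory:

- **Smoothness.** From the stacked, per-group-centered between- and
  within-stratum residual fields, v̄ = node-average of the squared gradient
  of variance-normalized residuals; FWHM = sqrt(4 ln 2 / v̄) in node units.
  Perfectly smooth residuals (v̄ → 0) are reported as infinite smoothness,
  which collapses the threshold to the scalar F quantile.
- **Threshold.** The critical value u* is the smallest u whose expected
  suprathreshold Euler characteristic, sf_F(u) + R·rho1(u) with resels
  R = (Q−1)/FWHM, equals alpha = 0.05; solved by bisection to 1e-6. The 1D
  EC density of an F field with df (k, v) is
  sqrt(4 ln 2/(2 pi)) · Gamma((v+k−1)/2)/(Gamma(v/2)Gamma(k/2)) · sqrt(2) ·
  (ku/v)^((k−1)/2) (1+ku/v)^(−(v+k−2)/2); for k = 1 this is exactly twice
  the one-sided T-field density at sqrt(u), as the F = T² identity
  requires — the identity that caught a coefficient error during
  development, alongside the permutation oracle.
- **Permutation oracle.** The (1−alpha) quantile of the max-over-nodes F
  under group-label permutation (group, interaction) or within-subject
  pre/post flips (time), with exact enumeration whenever the number of
  distinct rearrangements does not exceed `n_perm`. On matched-smoothness
  Gaussian nulls the two thresholds agree within a few percent and the RFT
  familywise error rate is 5% ± Monte-Carlo error (the acceptance suite
  verifies both on 2000 simulated cohorts at n = 14/11).
- **Clusters.** Maximal runs of nodes with F > u*, reported with half-open
  ranges and the cluster maximum. Threshold-level inference only — no
  cluster-extent p-values.

## Cohort statistics (`stats`)

- **Outlier screen.** z = (x − mean)/sd (sample sd), excluded where
  |z| ≥ 2.5, single pass per parameter and group, no re-iteration.
- **Mixed ANOVA.** Same engine as the SPM fields at Q = 1; reported with
  partial eta squared = F·df1/(F·df1 + df2). The interaction p is the
  between-group "difference" column of a pre/post comparison table.
- **Mixed MANOVA.** On the within-subject contrast variables d = post − pre
  of each dependent variable: a cell-means GLM on group gives the error
  SSCP E (df N−2) and, per single-df contrast (time: unweighted grand mean
  of d; interaction: group difference of d), the hypothesis SSCP H.
  Wilks' Lambda = det(E)/det(E+H), converted with Rao's F approximation
  (exact here since s = 1), multivariate partial eta squared
  = 1 − Lambda^(1/s) = 1 − Lambda. Designs with more within factors than
  time are out of scope of this operation; the effect-size identities the
  pipeline reproduces depend only on the single-df machinery. A singular E
  raises with its condition number.
- **Paired tests.** t on differences with d = mean(diff)/sd(diff), so
  d = t/sqrt(n). Sidedness is hypothesis-dependent and configurable:
  one-sided in the hypothesized improvement direction for the intervention
  group, two-sided otherwise. DV bundles for the MANOVA are caller-chosen.

## Muscle DTI (`tract`)

- **Tensor fit.** Log-linear least squares of ln(S_i/S0) = −b gᵢᵀDgᵢ over
  ≥ 6 non-collinear unit gradients; negative eigenvalues are clamped to
  zero with a warning. FA = sqrt(3/2)·‖lambda − mean‖/‖lambda‖.
- **Tracking.** Deterministic streamlines integrate the principal-
  eigenvector field with classical fixed-step RK4, bidirectionally from
  each seed, with the eigenvector sign aligned to the previous direction at
  every stage evaluation. Tensors are interpolated component-wise
  (trilinear) before eigen-decomposition — smoother than nearest-neighbour
  eigenvectors. The combined RK4 increment is used raw: renormalizing it
  makes the stepping equivalent to chord-stepping and demotes the scheme to
  second order (observed error ratio 4 instead of ~16 per step halving).
- **Stopping rules** (all configurable, defaults provisional in the range
  used for whole-muscle tractography): leave the mask, FA outside
  [0.05, 0.6], turning angle > 30 deg/step, length outside [10, 200] mm;
  step 1 mm. Seeding is one seed per masked voxel center in deterministic
  order, optionally subsampled at a uniform stride.
- **Fascicle metrics.** Mean streamline arc length; unique traversed voxel
  count × voxel volume ("tract volume", the tractography-tool convention
  for fascicle volume); length-weighted mean FA along paths.

## Synthetic generators (`synth`)

The generators produce data with the statistical structure the analysis
assumes, with known ground truth returned alongside every output. All
randomness flows from a single integer seed through spawned
`numpy.random.SeedSequence` streams in a documented order, so adding a
parameter never reorders existing draws.

- **Active trials.** Trapezoidal velocity per movement (ramp over
  `accel_time`, plateau at the commanded speed, ramp down; closed-form
  kinematics, so the commanded ROM is met exactly), n_reps out-and-back
  cycles, torque a Gaussian-in-angle bell (peak, optimum, width 35 deg
  default) plus additive Gaussian noise (0.25 Nm default). The bell is a
  stand-in for the unimodal torque-angle curves of this joint, not a claim
  about their true shape; a training effect is injected as a peak gain plus
  a rightward optimum shift, which concentrates the group×time difference
  in the inner ROM.
- **Passive trials.** Angle advances at 10 deg/s; torque follows the
  exponential model; motion reverses at the noiseless 9 Nm crossing or the
  angle cap, whichever is first; n cycles give 2n directional segments.
- **Cohorts.** Per-subject random intercepts (between-subject SD, default
  8 Nm for torque-scale parameters) plus occasion noise (within-subject SD,
  default 2 Nm), intervention post means shifted by a percent effect.
  Defaults follow the study conditions: n = 14 intervention / 11 control
  and the cohort's body mass distribution (84.8 ± 11.3 kg).
- **DTI phantom.** Cylindrical mask, straight (optionally pennate) or
  circular-arc fascicles; axially symmetric tensors whose principal axis is
  the local tangent and whose eigenvalue ratio solves the FA equation in
  closed form (generated FA matches the target to machine precision);
  principal eigenvalue 1.7e-3 mm²/s; optional DWI signals over 48
  Fibonacci-sphere directions at b = 400 s/mm² with Gaussian or Rician
  noise. The slab thickness is scaled by cos(pennation) so the oblique path
  length equals the requested fascicle length.

What the generators do **not** emulate: device compliance and inertial
artifacts, torque-velocity coupling, EMG/passivity confirmation,
viscoelastic (time-dependent) passive behaviour, MRI k-space artifacts,
partial-volume and susceptibility effects, or anatomically curved
pennate-fan geometry. Passing tests therefore demonstrate correctness of
the computations under the stated models, not robustness to every artifact
of real recordings.

## Problem sizes and published-value reproduction

The test and acceptance suites run at the study's scale where that is
cheap (n = 14/11 cohorts, Q = 101 nodes, 2000 null simulations for the
familywise calibration, 200 fit-recovery seeds, 150-seed phantom
tractography on a 16×16×48 grid). Subject-level raw data is not shipped;
the published group-level summaries are bundled as plain-text data and the
pipeline recomputes their derived columns (percent change, partial eta
squared, the 1 − Lambda identity, the d ↔ p consistency of paired tests)
with the same routines used on synthetic cohorts. Two printed control-group
percent changes are sign-dropped in the source tables and are flagged, not
reproduced; FA-row percent changes reproduce only within the rounding of
their 3-decimal means.

## Known limitations

- The e-function's exact published form and the submaximal ROM threshold
  are conventions adopted here (configurable), not values fixed by the
  protocol.
- RFT assumes smooth Gaussian component fields; at very low smoothness
  (FWHM ≲ 3 nodes) the threshold becomes conservative relative to the
  permutation oracle.
- The MANOVA operation covers one between and one two-level within factor
  with arbitrary DV count; higher-order within designs are not implemented.
- Tractography assumes a single coherent fiber population per voxel (no
  crossing-fiber model), appropriate for muscle.
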