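# Methods

This note documents the models, conventions and numerical choices behind
`gaitdiff`, and what its synthetic cohorts can and cannot tell you about
real motion-capture data.

## The analysis being reproduced

The package implements a complete group-comparison pipeline for treadmill
walking kinematics in knee osteoarthritis (OA) research:

1. 3D marker trajectories at 120 Hz → zero-lag low-pass filtering →
   rigid-body segment poses → joint-coordinate-system angles;
2. kinematic gait events → 100-point time-normalized gait cycles
   (60 stance + 40 swing points);
3. eight discrete variables per waveform × 14 waveforms → a 112-column
   feature vector per subject;
4. univariate statistics: one-way ANOVA, Cohen's d, Holm–Bonferroni
   adjustment, significance rule *adjusted p* < 0.05 AND *d* > 0.8;
5. multivariate classification: PCA scores or raw variables, ranked by
   descending d, fed incrementally into a linear SVM (soft margin c = 1)
   under stratified 10-fold cross-validation.

## Kinematics

**Filtering.** A 2nd-order recursive Butterworth low-pass at 10 Hz is
applied forward–backward (`scipy.signal.filtfilt`), giving zero phase lag
and a dual-pass gain of |H(f)|². The digital (bilinear, prewarped) design
matches the analog closed form 1/(1+(f/fc)⁴) exactly at and below the
cutoff; in the stopband it attenuates *more* than the closed form, which
the tests treat as an upper bound. No cutoff adjustment is made for the
dual pass: "10 Hz 2nd-order" is interpreted per pass, the common convention
in gait laboratories.

**Pose estimation.** Per frame, each segment's rotation and translation
are the least-squares rigid transform from the calibrated technical-cluster
configuration to the observed one, solved by SVD of the cross-dispersion
matrix with reflection correction on the smallest singular value. Batched
3×3 SVDs make whole-trial tracking vectorized. Collinear or <3-marker
configurations raise a degenerate-configuration error.

**Calibration.** One static frame with 14 anatomical landmarks defines
joint centres (knee and ankle as marker midpoints; hip as the greater
trochanter displaced 70 mm medially along the inter-trochanter line — a
fixed conventional offset, since the marker set gives no better estimate)
and segment frames: X to the subject's right, Y anterior, Z up, with
longitudinal axes joining joint centres and the foot frame horizontalized
against the lab vertical. The cluster-to-anatomical mapping is stored so
walking trials need only the clusters.

**Joint angles.** Cardan decomposition of R_proximal⁻¹·R_distal in the
sequence flexion (proximal mediolateral axis) → ab/adduction (floating
axis) → axial rotation (distal longitudinal axis); equivalently an
intrinsic X–Y–Z sequence in these frames. Pelvis and foot are decomposed
against the lab frame; the foot reports only sagittal and transverse
planes. Left-side frontal and transverse angles are mirrored so adduction
and internal rotation are positive on both sides; with that convention,
knee frontal values are adduction-positive and the published negative knee
values read as abduction. Frames with the floating axis within 0.5° of
alignment are flagged but still return angles.

## Events and normalization

Heel strike is the per-cycle *most anterior* position of the superior
calcaneal marker; toe-off the *most posterior* position of the anterior
shoe marker — the standard kinematic definitions for treadmill gait.
Detection uses local extrema with (i) a prominence criterion of ¼ of the
signal range, rejecting the small anterior wobble the heel marker shows
around toe-off when the foot pitches while its translation is momentarily
stationary, and (ii) a refractory period of half the median inter-peak
interval. Toe-offs are kept only if they fall strictly between consecutive
heel strikes.

Each stride is resampled by linear interpolation: heel strike → toe-off
onto 60 points, toe-off → next heel strike onto 40 points (the swing grid
starts one normalized step after toe-off so point 60 is not duplicated).
Point 1 is the touchdown sample and point 60 the toe-off sample. Analysis
uses the first ten complete consecutive cycles after skipping two settling
strides; the settling count is a configuration default, not a quantity
reported for the original protocol.

## Discrete variables and the feature matrix

Per waveform: angle at touchdown (point 1), stance max/min peaks
(points 1–60), angle at toe-off (point 60), swing max/min peaks
(points 61–100), and stance/swing ranges of motion defined as phase
max − min (peak-to-peak, guaranteeing ROM ≥ 0). Variables are averaged
over the ten strides; because ROM is linear in the per-stride extrema the
averaged table still satisfies ROM = max − min exactly.

One side enters the analysis per subject: the affected side (unilateral
OA), the recorded most-affected side (bilateral OA), or a seeded uniformly
random side (controls). Column order of the 112-column matrix is frozen:
joint-major (ankle, knee, hip, pelvis, foot), plane-minor (sagittal,
frontal, transverse; no foot frontal), variable-innermost — e.g.
`knee_frontal_touchdown`. That gives 40 sagittal, 32 frontal and 40
transverse columns.

## Statistics

Columns are standardized to zero mean and unit *sample* SD (n−1). PCA is
computed by SVD of the standardized matrix: eigenvalues are squared
singular values over (n−1) and sum to the column count; at most n−1
components carry variance, so scores and eigenvalues are truncated there
(e.g. 99 retained dimensions for 100 subjects). The SVD sign ambiguity is
pinned by making each component's largest-magnitude loading positive.

Cohen's d uses **average-variance pooling**, d = |m₁−m₂| / √((s₁²+s₂²)/2).
This choice is load-bearing: it reproduces all six published group
effect sizes (0.89, 0.85, 0.81, 1.27, 1.15, 1.43) from the printed means
and SDs to two decimals, whereas (n−1)-weighted pooling does not (it gives
1.39, not 1.43, for the control hip comparison with n = 18 vs 25).

Holm–Bonferroni is the step-down adjustment over the family of all 112
variables within one group comparison (the family scope per comparison is
the package's reading; adjusting across comparisons jointly would be more
conservative). A variable is "significant and meaningful" when adjusted
p < 0.05 and d > 0.8.

## Classification

Features (raw variables or PC scores) are ranked by descending d and added
one at a time; each feature count k is scored by stratified 10-fold CV of
a linear SVM with c = 1, with standardization fitted inside training folds.
The optimal k is the smallest maximizer of the fold-mean accuracy curve
(parsimony tie-break; fold-mean rather than pooled-prediction accuracy).
Stratified folds are used because the study's class sizes (45/55, 18/25)
make unstratified folds risk class-free test sets.

Two ranking modes are exposed. `paper-faithful` ranks once on the full
data before CV — the procedure as typically described, which leaks label
information into the ranking and is optimistically biased on uninformative
data (asserted as a property test). `leakage-safe` re-ranks within every
training fold. Both are reported; no attempt is made to decide which
produced the originally published 98–100 % accuracies, which in any case
depend on the undeposited cohort data.

## The synthetic cohort generator

**What it emulates.** The study conditions are the defaults: group sizes
45/55 OA males/females and 18/25 controls; walking speeds uniform in
1.0–1.3 m/s; stance fraction 0.6; ten analysed strides; group effects on
exactly three variables — knee frontal touchdown, knee frontal swing max,
hip frontal stance max — with the published per-group means and SDs, and a
single shared mean everywhere else. Untargeted variables get a
between-subject SD of 3° and all variables a stride-to-stride SD of 1°;
neither within-subject variability nor untargeted between-subject spread
is reported for the original cohort, so these are realistic fixed choices,
not calibrated values.

**Waveform level.** Each cycle is a monotone piecewise-cubic (PCHIP) curve
through fixed per-waveform control points on the 100-point grid whose
values *are* the discrete variables (touchdown at point 1, designated
stance/swing extrema, toe-off at point 60). Monotonicity between control
points means the curve's phase extrema sit exactly at the control points,
so an injected value of `group mean + subject effect + stride noise` is
realized exactly at extraction. Shape-only auxiliary points are clipped
strictly inside the span of their phase's variable-carrying points so they
can never become an extremum. Curve shapes are stylized adult walking
patterns; only the discrete variables carry group signal. Control points
drawn independently can cross in rare tails (~1–2 % for the default
margins), in which case the generator's `realized` table reports the
actual extremum; both the intended and realized ground truth are returned.

A structural consequence of independent draws: injecting a mean difference
into a phase extremum necessarily shifts that phase's ROM by the same
amount (diluted by the ROM's larger SD, d ≈ 0.65–0.7 for the default
effects). In real cohorts, whole-curve correlation between a subject's
extrema suppresses ROM differences; the generator deliberately draws
variables independently, so its ROM columns respond where real ones did
not. Tests account for these derived partners explicitly.

**Marker level.** A 7-segment chain (pelvis, thighs, shanks, feet) is
driven by smooth periodic joint-angle curves built from the same waveform
templates, with 25 cluster/heel markers plus two toe markers rigidly
attached and optional isotropic Gaussian marker noise (default 0.5 mm).
The static trial is a symmetric neutral stance whose anatomical frames are
lab-aligned, so calibration, tracking and angle decomposition are exact up
to noise and filtering. Knee flexion drives the chain with a physiological
sign; ground truth is always what the chain realizes. Group effects are
injected as cosine-squared bumps (half-width 0.12 cycle) localized at the
target variable's phase; foot-segment variables, being derived from the
whole chain, do not support direct injection. Ground-truth heel-strike and
toe-off frames are the per-cycle extrema of the noiseless heel/toe marker
anterior coordinate; ground-truth discrete variables come from the driven
curves segmented at those frames. Running the full marker pipeline on
noiseless recordings reproduces them within ~1.5° (the residual reflects
10 Hz filtering of the sharper template features and ±1-frame event
placement).

**What passing tests do not show.** The generator has rigid segments, no
soft-tissue artefact, no marker occlusion or gap, stylized waveform
shapes, independent normal effects, and sex/OA differences confined to the
injected table. Pipeline correctness on it demonstrates the numerics and
the statistical machinery, not robustness to the failure modes of real
optical capture.

## Problem sizes and determinism

All randomness flows from a single seed through hierarchical
`SeedSequence` spawning (cohort → subject), so identical specifications
are bit-identical and cohorts are reproducible per subject. The test suite
uses cohorts of 4–1,000 subjects per group, chosen so each assertion's
sampling error is small against its tolerance; the parameter-recovery
checks use n = 200–500 per group, and the end-to-end recovery of the three
injected effects uses n = 500 per group. The acceptance script's effect
sizes are closed-form computations from the built-in group statistics and
involve no simulation.

## Known limitations

- No C3D reader/writer; marker data travel in the documented TSV dialect.
- Hip joint centre by fixed 70 mm medial offset; no functional calibration.
- Ankle inversion/eversion axis follows the generic JCS frames above, not
  a subject-specific anatomical axis.
- Marker gap filling is out of scope (trajectories must be complete).
- The true hip frontal stance-max effect (d ≈ 0.81) sits essentially on
  the d > 0.8 flag threshold, so whether that variable is *flagged* in a
  finite synthetic cohort is a near coin flip at any sample size; its
  ranking and Holm-adjusted p are stable and are what the tests assert.
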