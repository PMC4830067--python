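# gaitdiff

A tested, reusable pipeline for comparing walking gait kinematics between
groups — built for the question of how men and women with and without knee
osteoarthritis (OA) differ in lower-limb joint motion, and usable for any
two-group gait comparison with the same structure.

It takes 3D motion-capture marker trajectories (or pre-computed joint-angle
cycles) and produces:

- **joint angles**: zero-lag 10 Hz Butterworth filtering, SVD rigid-body
  segment poses from technical marker clusters, and joint-coordinate-system
  Cardan angles (flexion → ab/adduction → axial rotation) for ankle, knee
  and hip, plus pelvis and foot segment angles in the lab frame;
- **gait cycles**: heel strikes from the most anterior position of the
  superior calcaneal marker, toe-offs from the most posterior position of
  the toe marker, and each stride time-normalized to 100 points
  (60 stance + 40 swing);
- **features**: eight discrete variables per waveform (touchdown, stance
  max/min, toe-off, swing max/min, stance/swing ROM), averaged over ten
  consecutive strides, one side per subject, assembled into an n×112
  feature matrix;
- **statistics**: one-way ANOVA with Holm–Bonferroni adjustment and
  Cohen's d with average-variance pooling,
  d = |m₁−m₂| / √((s₁²+s₂²)/2), flagging variables with adjusted p < 0.05
  and d > 0.8;
- **classification**: raw variables or PCA scores (SVD of the standardized
  matrix, coefficients V, eigenvalues L, scores Z) ranked by descending d
  and added incrementally to a linear SVM (c = 1) under stratified 10-fold
  cross-validation, reporting the accuracy-vs-k curve and the optimal
  feature count.

Because cohort data of this kind are rarely deposited, the package includes
a first-class synthetic-cohort generator (`gaitdiff.synthetic`) producing
either joint-angle cycles or full marker-level recordings of a 7-segment
walking model, with known injected group effects and ground-truth gait
events — so every stage of the pipeline is testable end to end. Its
defaults reproduce the reference study's conditions: 45/55 OA males/females,
18/25 controls, speeds in 1.0–1.3 m/s, and sex differences on exactly three
variables (knee frontal-plane angle at touchdown and swing maximum, hip
frontal-plane stance maximum) with the published group means and SDs.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate the default study-sized cohort at the waveform level, then run the
full analysis comparing sexes within the OA and control groups:

```bash
gaitdiff simulate --out cohort/ --level waveforms --seed 7
gaitdiff run --input cohort/ --out results/ --compare sex --seed 7
```

which prints (abridged):

```
{
  "sex_within_OA": {
    "n_significant": 2,
    "significant": ["knee_frontal_touchdown", "knee_frontal_swing_max"]
  },
  "sex_within_control": {
    "n_significant": 4,
    "significant": ["knee_frontal_touchdown", "knee_frontal_swing_max",
                    "hip_sagittal_rom_stance", "hip_frontal_stance_max"]
  }
}
{
  "raw_sex_within_OA":      {"optimal_k": 3,  "max_accuracy": 0.81},
  "raw_sex_within_control": {"optimal_k": 7,  "max_accuracy": 0.95},
  "pca_sex_within_OA":      {"optimal_k": 40, "max_accuracy": 0.92, "variance_explained": 0.49},
  "pca_sex_within_control": {"optimal_k": 28, "max_accuracy": 0.975, "variance_explained": 0.81}
}
```

Reading this: in the simulated OA group (45 men, 55 women) the univariate
pathway recovers two of the three injected sex differences above both
thresholds (the third, hip frontal stance max, has a true effect size of
0.81 — right on the d > 0.8 boundary, so its flag is sample-dependent even
though its adjusted p is clearly significant). The multivariate pathway
separates the sexes at 81 % CV accuracy from the top 3 ranked discrete
variables, and at 92 % from 40 PC scores explaining 49 % of the variance.
`results/` contains the feature matrix, per-comparison effect-size tables
(group means, SDs, d, raw and adjusted p, flags), selection curves as JSON,
and a run log.

The same `run` command accepts a marker-level directory
(`gaitdiff simulate --level markers`, or your own trials in the documented
TSV dialect: columns `frame  marker_id  x  y  z` in mm, one static and one
walking trial per subject) and will then execute the full kinematic chain:
filter → calibrate → track → angles → events → cycles → features → stats.

As a library:

```python
from gaitdiff import CohortSpec, generate_waveform_cohort, cohens_d
from gaitdiff.pipeline import PipelineConfig, features_from_cycles, analyze_groups

cohort = generate_waveform_cohort(CohortSpec(seed=7))
X = features_from_cycles(cohort.cycles, cohort.subjects, PipelineConfig())
table = analyze_groups(X, compare="sex")["sex_within_OA"]
print(table.loc["knee_frontal_touchdown", ["d", "p_adjusted", "significant"]])
```

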