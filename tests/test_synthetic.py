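"""The synthetic cohort generators: determinism, exactness of injected
effects, parameter recovery and marker-level ground truth."""

import numpy as np
import pytest

from gaitdiff.errors import InvalidSpecError
from gaitdiff.features import extract_discrete
from gaitdiff.kinematics import CLUSTER_MARKERS, fit_rigid_transform
from gaitdiff.schema import WAVEFORMS
from gaitdiff.stats import cohens_d
from gaitdiff.synthetic import (
    CohortSpec,
    generate_marker_cohort,
    generate_waveform_cohort,
    static_marker_set,
)


def _group_d(cohort, col, g1, g2, table="realized"):
    values = getattr(cohort, table)[col]
    groups = cohort.subjects["group"]
    a = values[(groups == g1).values]
    b = values[(groups == g2).values]
    return cohens_d(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------

def test_invalid_specs_rejected():
    with pytest.raises(InvalidSpecError):
        CohortSpec(group_sizes={"OA_male": 1}).validate()
    with pytest.raises(InvalidSpecError):
        CohortSpec(stride_noise_sd=-1.0).validate()
    with pytest.raises(InvalidSpecError):
        CohortSpec(stance_fraction=1.5).validate()
    with pytest.raises(InvalidSpecError):
        CohortSpec(
            effect_table={("knee", "frontal", "touchdown"): {"OA_male": (0.0, -2.0)}}
        ).validate()
    with pytest.raises(InvalidSpecError):
        CohortSpec(speed_range=(0.0, 5.0)).validate()


# ---------------------------------------------------------------------------
# waveform level
# ---------------------------------------------------------------------------

def test_waveform_generation_is_bit_deterministic():
    spec = CohortSpec(seed=5, group_sizes={"OA_male": 3, "OA_female": 3})
    a = generate_waveform_cohort(spec)
    b = generate_waveform_cohort(CohortSpec(seed=5, group_sizes={"OA_male": 3, "OA_female": 3}))
    assert a.subjects.equals(b.subjects)
    for sid in a.cycles:
        for wf in a.cycles[sid]:
            assert np.array_equal(a.cycles[sid][wf], b.cycles[sid][wf])
    c = generate_waveform_cohort(CohortSpec(seed=6, group_sizes={"OA_male": 3, "OA_female": 3}))
    assert not np.array_equal(
        a.cycles["S0000"][("knee", "frontal")], c.cycles["S0000"][("knee", "frontal")]
    )


def test_cycles_have_100_points_and_phase_split():
    spec = CohortSpec(seed=1, group_sizes={"OA_male": 2, "OA_female": 2})
    cohort = generate_waveform_cohort(spec)
    for per_wave in cohort.cycles.values():
        assert set(per_wave) == set(WAVEFORMS)
        for arr in per_wave.values():
            assert arr.shape == (spec.strides_per_subject, 100)
            assert np.all(np.isfinite(arr))


def test_zero_effect_zero_noise_cohort_is_exactly_at_shared_means():
    """With no injected differences, zero between-subject SD and zero
    stride noise, every subject's every discrete variable equals the shared
    (template) value exactly."""
    spec = CohortSpec(
        seed=2,
        group_sizes={"OA_male": 3, "control_female": 3},
        effect_table={},
        default_subject_sd=0.0,
        stride_noise_sd=0.0,
    )
    cohort = generate_waveform_cohort(spec)
    assert (cohort.realized.std(axis=0) < 1e-12).all()
    assert np.allclose(cohort.realized.to_numpy(), cohort.intended.to_numpy(), atol=1e-12)
    groups = cohort.subjects["group"]
    male = cohort.realized[(groups == "OA_male").values].mean()
    female = cohort.realized[(groups == "control_female").values].mean()
    assert np.allclose(male.to_numpy(), female.to_numpy(), atol=1e-12)


def test_discrete_extraction_matches_generator_ground_truth():
    """Running the extraction pipeline over the generated cycles reproduces
    the generator's realized table exactly (the control points are the
    discrete variables)."""
    spec = CohortSpec(seed=3, group_sizes={"OA_male": 2, "OA_female": 2})
    cohort = generate_waveform_cohort(spec)
    for sid, per_wave in cohort.cycles.items():
        for (joint, plane), arr in per_wave.items():
            means = {
                var: np.mean([extract_discrete(c)[var] for c in arr])
                for var in ("touchdown", "stance_max", "swing_min", "rom_swing")
            }
            for var, val in means.items():
                assert val == pytest.approx(
                    cohort.realized.loc[sid, f"{joint}_{plane}_{var}"], abs=1e-9
                )


def test_published_effects_converge_to_published_d():
    """Injecting the published knee frontal touchdown group statistics
    yields an empirical Cohen's d near 0.89 at large n."""
    spec = CohortSpec(seed=4, group_sizes={"OA_male": 400, "OA_female": 400})
    cohort = generate_waveform_cohort(spec)
    d = _group_d(cohort, "knee_frontal_touchdown", "OA_male", "OA_female")
    assert d == pytest.approx(0.89, abs=0.15)


def test_injected_d_recovered_and_consistent_with_stored_draws():
    """A custom injected effect of d = 1.0 on one variable is recovered
    within +/-0.2 at n = 200/group, and the realized-group d agrees with a
    direct recomputation from the generator's stored subject draws."""
    table = {
        ("ankle", "frontal", "touchdown"): {
            "OA_male": (0.0, 3.0),
            "OA_female": (3.0, 3.0),
        }
    }
    spec = CohortSpec(
        seed=9, group_sizes={"OA_male": 200, "OA_female": 200}, effect_table=table
    )
    cohort = generate_waveform_cohort(spec)
    d_real = _group_d(cohort, "ankle_frontal_touchdown", "OA_male", "OA_female")
    d_intent = _group_d(cohort, "ankle_frontal_touchdown", "OA_male", "OA_female", "intended")
    assert d_real == pytest.approx(1.0, abs=0.2)
    assert d_real == pytest.approx(d_intent, abs=0.05)


def test_analytic_parameter_recovery_at_large_n():
    """For injected (delta mean, SD) the empirical d converges to
    delta/SD; checked within +/-0.1 at n = 500/group."""
    table = {
        ("hip", "transverse", "swing_min"): {
            "OA_male": (-7.0, 4.0),
            "OA_female": (-1.0, 4.0),
        }
    }
    spec = CohortSpec(
        seed=12, group_sizes={"OA_male": 500, "OA_female": 500}, effect_table=table
    )
    cohort = generate_waveform_cohort(spec)
    d = _group_d(cohort, "hip_transverse_swing_min", "OA_male", "OA_female")
    assert d == pytest.approx(6.0 / 4.0, abs=0.1)


def test_rom_nonnegative_and_consistent():
    spec = CohortSpec(seed=8, group_sizes={"OA_male": 5, "control_male": 5})
    cohort = generate_waveform_cohort(spec)
    for joint, plane in WAVEFORMS:
        rom = cohort.realized[f"{joint}_{plane}_rom_stance"]
        hi = cohort.realized[f"{joint}_{plane}_stance_max"]
        lo = cohort.realized[f"{joint}_{plane}_stance_min"]
        assert (rom >= -1e-12).all()
        assert np.allclose(rom, hi - lo)


# ---------------------------------------------------------------------------
# marker level
# ---------------------------------------------------------------------------

def test_marker_generation_is_deterministic():
    spec = CohortSpec(seed=21, group_sizes={"OA_male": 2, "OA_female": 2})
    r1, t1 = generate_marker_cohort(spec)
    r2, t2 = generate_marker_cohort(CohortSpec(seed=21, group_sizes={"OA_male": 2, "OA_female": 2}))
    for a, b in zip(r1, r2):
        assert a.subject_id == b.subject_id
        for m in a.walking_markers:
            assert np.array_equal(a.walking_markers[m].positions, b.walking_markers[m].positions)


def test_noiseless_rigid_fit_recovers_constructed_pose(noiseless_marker_cohort):
    """Markers are rigidly attached: fitting any technical cluster returns
    the constructed segment pose with orthonormal rotation and ~zero
    residual."""
    recordings, truths = noiseless_marker_cohort
    rec = recordings[0]
    gt = truths[rec.subject_id]
    static = static_marker_set()
    for segment in ("pelvis", "right_thigh", "left_shank", "right_foot"):
        names = CLUSTER_MARKERS[segment]
        ref = np.array([static[m] for m in names])
        frame = 300
        cur = np.array([rec.walking_markers[m].positions[frame] for m in names])
        R, t, res = fit_rigid_transform(ref, cur)
        assert res < 1e-6
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
        R_true = gt.poses[segment][0][frame]
        assert np.allclose(R, R_true, atol=1e-6)


def test_marker_recording_duration_and_rate(noiseless_marker_cohort):
    recordings, truths = noiseless_marker_cohort
    for rec in recordings:
        gt = truths[rec.subject_id]
        n = next(iter(rec.walking_markers.values())).positions.shape[0]
        # at least 10 analysable strides after settling
        assert n >= (10 + 2) * gt.frames_per_stride
        rates = {t.sampling_rate for t in rec.walking_markers.values()}
        lengths = {t.positions.shape[0] for t in rec.walking_markers.values()}
        assert rates == {rec.sampling_rate} and len(lengths) == 1


def test_noisy_events_within_one_frame(noisy_marker_cohort):
    """With 1 mm marker noise, detected events match ground truth within
    +/-1 frame for >=95 % of cycles."""
    from gaitdiff.events import detect_heel_strikes, detect_toe_offs
    from gaitdiff.filtering import butterworth_lowpass

    recordings, truths = noisy_marker_cohort
    hits = total = 0
    for rec in recordings:
        gt = truths[rec.subject_id]
        for side, prefix in (("left", "L"), ("right", "R")):
            heel = butterworth_lowpass(rec.walking_markers[f"{prefix}_HEEL_SUP"].positions)[:, 1]
            toe = butterworth_lowpass(rec.walking_markers[f"{prefix}_TOE"].positions)[:, 1]
            hs = detect_heel_strikes(heel)
            to = detect_toe_offs(toe)
            for x in gt.heel_strikes[side]:
                total += 1
                hits += np.min(np.abs(hs - x)) <= 1
            for x in gt.toe_offs[side]:
                total += 1
                hits += np.min(np.abs(to - x)) <= 1
    assert hits / total >= 0.95
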