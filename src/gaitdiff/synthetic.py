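"""Synthetic gait cohorts with known injected group effects.

Two fidelity levels stand in for a motion-capture study cohort:

* **Waveform level** — per-subject, per-stride 100-point joint-angle cycles
  for the 14 joint/plane waveforms. Each cycle is a monotone piecewise-cubic
  (PCHIP) curve through fixed per-waveform control points; the control-point
  values *are* the discrete variables, so an injected group mean, a normal
  between-subject effect and normal stride-to-stride noise are realized
  exactly at the extraction points. Shape-only auxiliary control points are
  clipped strictly inside the span of the variable-carrying points of their
  phase so they can never become a phase extremum.

* **Marker level** — a 7-segment rigid kinematic chain (pelvis, thighs,
  shanks, feet) driven by periodic joint-angle curves, with 25 cluster/heel
  markers plus toe markers rigidly attached, walking on a virtual treadmill
  at 120 Hz. Heel-strike and toe-off ground truth are the per-cycle
  anterior/posterior extrema of the constructed heel and toe markers.

The default cohort reproduces the study conditions: group sizes 45/55 OA
males/females and 18/25 male/female controls, walking speeds drawn from
1.0-1.3 m/s, ten analysed strides per subject, and group effects on exactly
three variables — knee frontal-plane angle at touchdown and maximum peak
during swing, and hip frontal-plane maximum peak during stance — with the
published group means and SDs; every other variable shares one mean across
groups.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator

from . import kinematics as kin
from .errors import InvalidSpecError
from .events import GaitEvents, pair_events, segment_normalize
from .features import average_strides, extract_discrete
from .schema import (
    FEATURE_COLUMN_NAMES,
    MarkerTrajectory,
    POINT_VARIABLES,
    SubjectRecording,
    WAVEFORMS,
)

#: Published group statistics (mean, SD in degrees) for the three variables
#: that differ between sexes; groups are OA_male / OA_female /
#: control_male / control_female.
STUDY_EFFECTS: dict[tuple[str, str, str], dict[str, tuple[float, float]]] = {
    ("knee", "frontal", "touchdown"): {
        "OA_male": (-1.37, 3.80),
        "OA_female": (-4.88, 4.06),
        "control_male": (-2.02, 2.96),
        "control_female": (-5.75, 2.91),
    },
    ("knee", "frontal", "swing_max"): {
        "OA_male": (-1.24, 3.86),
        "OA_female": (-4.66, 4.16),
        "control_male": (-1.77, 2.89),
        "control_female": (-5.20, 3.07),
    },
    ("hip", "frontal", "stance_max"): {
        "OA_male": (4.86, 3.73),
        "OA_female": (7.67, 3.21),
        "control_male": (5.41, 1.94),
        "control_female": (8.69, 2.61),
    },
}

STUDY_GROUP_SIZES = {
    "OA_male": 45,
    "OA_female": 55,
    "control_male": 18,
    "control_female": 25,
}

#: Control points (cycle point 1-100, role, base value in degrees) per
#: waveform. Stance occupies points 1-60, swing 61-100. Shapes are stylized
#: adult walking patterns; only the discrete variables carry group signal.
WAVEFORM_TEMPLATES: dict[tuple[str, str], tuple[tuple[int, str, float], ...]] = {
    ("ankle", "sagittal"): (
        (1, "touchdown", 0.0), (35, "stance_max", 10.0), (57, "stance_min", -15.0),
        (60, "toeoff", -12.0), (61, "aux", -13.0), (66, "swing_min", -16.0),
        (85, "swing_max", 4.0), (100, "aux", 0.0),
    ),
    ("ankle", "frontal"): (
        (1, "touchdown", 0.0), (20, "stance_max", 4.0), (50, "stance_min", -4.0),
        (60, "toeoff", 2.0), (61, "aux", 1.0), (75, "swing_max", 6.0),
        (90, "swing_min", -3.0), (100, "aux", 0.0),
    ),
    ("ankle", "transverse"): (
        (1, "touchdown", -2.0), (25, "stance_max", 5.0), (50, "stance_min", -6.0),
        (60, "toeoff", 0.0), (61, "aux", 0.0), (75, "swing_max", 4.0),
        (90, "swing_min", -5.0), (100, "aux", -2.0),
    ),
    ("knee", "sagittal"): (
        (1, "touchdown", 5.0), (15, "stance_max", 20.0), (40, "stance_min", 4.0),
        (60, "toeoff", 15.0), (61, "aux", 17.0), (75, "swing_max", 60.0),
        (95, "swing_min", 3.0), (100, "aux", 5.0),
    ),
    ("knee", "frontal"): (
        (1, "touchdown", -3.3), (25, "stance_max", 8.0), (45, "stance_min", -15.0),
        (60, "toeoff", -4.0), (61, "aux", -12.0), (72, "swing_max", -3.0),
        (88, "swing_min", -16.0), (100, "aux", -12.0),
    ),
    ("knee", "transverse"): (
        (1, "touchdown", -3.0), (20, "stance_max", 6.0), (50, "stance_min", -9.0),
        (60, "toeoff", -2.0), (61, "aux", -3.0), (75, "swing_max", 5.0),
        (90, "swing_min", -8.0), (100, "aux", -4.0),
    ),
    ("hip", "sagittal"): (
        (1, "touchdown", 30.0), (10, "stance_max", 33.0), (50, "stance_min", -8.0),
        (60, "toeoff", 0.0), (61, "aux", 2.0), (63, "swing_min", 0.0),
        (82, "swing_max", 33.0), (100, "aux", 30.0),
    ),
    ("hip", "frontal"): (
        (1, "touchdown", -6.0), (28, "stance_max", 6.3), (55, "stance_min", -10.0),
        (60, "toeoff", -6.0), (61, "aux", -5.0), (68, "swing_min", -9.0),
        (92, "swing_max", -2.0), (100, "aux", -3.0),
    ),
    ("hip", "transverse"): (
        (1, "touchdown", 2.0), (30, "stance_max", 8.0), (55, "stance_min", -6.0),
        (60, "toeoff", -4.0), (61, "aux", -3.0), (75, "swing_max", 4.0),
        (90, "swing_min", -7.0), (100, "aux", 0.0),
    ),
    ("pelvis", "sagittal"): (
        (1, "touchdown", 8.0), (20, "stance_max", 11.0), (45, "stance_min", 5.0),
        (60, "toeoff", 8.0), (61, "aux", 8.0), (75, "swing_max", 11.0),
        (90, "swing_min", 5.0), (100, "aux", 8.0),
    ),
    ("pelvis", "frontal"): (
        (1, "touchdown", 0.0), (20, "stance_max", 5.0), (50, "stance_min", -5.0),
        (60, "toeoff", -2.0), (61, "aux", -2.0), (75, "swing_max", 4.0),
        (90, "swing_min", -4.0), (100, "aux", 0.0),
    ),
    ("pelvis", "transverse"): (
        (1, "touchdown", 4.0), (30, "stance_max", 7.0), (55, "stance_min", -6.0),
        (60, "toeoff", -5.0), (61, "aux", -5.0), (68, "swing_min", -7.0),
        (85, "swing_max", 6.0), (100, "aux", 3.0),
    ),
    ("foot", "sagittal"): (
        (1, "touchdown", 18.0), (6, "stance_max", 22.0), (55, "stance_min", -25.0),
        (60, "toeoff", -18.0), (61, "aux", -10.0), (68, "swing_min", -26.0),
        (88, "swing_max", 20.0), (100, "aux", 15.0),
    ),
    ("foot", "transverse"): (
        (1, "touchdown", -5.0), (25, "stance_max", 2.0), (50, "stance_min", -10.0),
        (60, "toeoff", -6.0), (61, "aux", -6.0), (78, "swing_max", 0.0),
        (90, "swing_min", -11.0), (100, "aux", -5.0),
    ),
}

AUX_SD_DEG = 1.0
AUX_CLIP_MARGIN_DEG = 0.25


def default_effect_table() -> dict:
    """The study's effect table: published means/SDs for the three
    sex-different variables; all other variables share their template base
    value across groups (handled implicitly)."""
    return copy.deepcopy(STUDY_EFFECTS)


@dataclass
class CohortSpec:
    """Conditions under which a synthetic cohort is generated."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_GROUP_SIZES)
    )
    effect_table: dict = field(default_factory=default_effect_table)
    strides_per_subject: int = 10
    default_subject_sd: float = 3.0  # deg, between-subject SD of untargeted variables
    stride_noise_sd: float = 1.0  # deg, within-subject stride-to-stride SD
    speed_range: tuple[float, float] = (1.0, 1.3)  # m/s
    stance_fraction: float = 0.6
    sampling_rate: float = 120.0  # Hz
    marker_noise_sd_mm: float = 0.5  # marker-level measurement noise
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise InvalidSpecError("group_sizes is empty")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise InvalidSpecError(f"group {g} has size {n} < 2")
            if "_" not in g or g.split("_", 1)[1] not in ("male", "female"):
                raise InvalidSpecError(
                    f"group label {g!r} must look like status_sex, e.g. OA_male"
                )
        for key, entry in self.effect_table.items():
            if key[:2] not in WAVEFORMS or key[2] not in POINT_VARIABLES:
                raise InvalidSpecError(f"unknown effect-table key {key}")
            for g, (mean, sd) in entry.items():
                if sd < 0:
                    raise InvalidSpecError(f"negative SD for {key} in group {g}")
        if self.strides_per_subject < 1:
            raise InvalidSpecError("strides_per_subject must be >= 1")
        if self.default_subject_sd < 0 or self.stride_noise_sd < 0:
            raise InvalidSpecError("SDs must be >= 0")
        if not (0.0 < self.stance_fraction < 1.0):
            raise InvalidSpecError("stance_fraction must lie in (0, 1)")
        lo, hi = self.speed_range
        if not (0.0 < lo <= hi < 3.0):
            raise InvalidSpecError("speed_range must lie within (0, 3)")
        if self.sampling_rate <= 0:
            raise InvalidSpecError("sampling_rate must be positive")
        if self.marker_noise_sd_mm < 0:
            raise InvalidSpecError("marker noise SD must be >= 0")


def _subject_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Subject labels, affected sides and walking speeds for one cohort."""
    rows = []
    idx = 0
    for group, n in spec.group_sizes.items():
        status, sex = group.split("_", 1)
        for _ in range(n):
            sid = f"S{idx:04d}"
            if status.lower() == "oa":
                status_lab = "OA"
                # unilateral left / unilateral right / bilateral, in the
                # study's observed proportions
                u = rng.random()
                if u < 0.43:
                    side, bilateral = "left", False
                elif u < 0.80:
                    side, bilateral = "right", False
                else:
                    side = "left" if rng.random() < 0.5 else "right"
                    bilateral = True
            else:
                status_lab, side, bilateral = "control", None, False
            speed = rng.uniform(*spec.speed_range)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "status": status_lab,
                    "sex": sex,
                    "affected_side": side,
                    "bilateral": bilateral,
                    "speed": speed,
                }
            )
            idx += 1
    return pd.DataFrame(rows).set_index("subject_id")


def _knot_arrays(spec: CohortSpec, group: str, waveform: tuple[str, str]):
    """Per-knot (mean, sd, is_aux) arrays for one waveform in one group."""
    template = WAVEFORM_TEMPLATES[waveform]
    means = np.empty(len(template))
    sds = np.empty(len(template))
    aux = np.zeros(len(template), dtype=bool)
    for i, (pt, role, base) in enumerate(template):
        if role == "aux":
            means[i], sds[i], aux[i] = base, AUX_SD_DEG, True
            continue
        entry = spec.effect_table.get((*waveform, role))
        if entry is not None and group in entry:
            means[i], sds[i] = entry[group]
        else:
            means[i], sds[i] = base, spec.default_subject_sd
    return means, sds, aux


def _clip_aux(values: np.ndarray, points: np.ndarray, aux: np.ndarray) -> np.ndarray:
    """Clip aux knots strictly inside the span of the variable-carrying
    knots of their phase (stance: points <= 60; swing: points >= 61)."""
    out = values.copy()
    for phase_mask in (points <= 60, points >= 61):
        var_idx = phase_mask & ~aux
        aux_idx = phase_mask & aux
        if not aux_idx.any() or not var_idx.any():
            continue
        lo = out[..., var_idx].min(axis=-1)
        hi = out[..., var_idx].max(axis=-1)
        span = hi - lo
        m = np.where(span > 2 * AUX_CLIP_MARGIN_DEG, AUX_CLIP_MARGIN_DEG, span / 2.0)
        clipped = np.clip(
            out[..., aux_idx], (lo + m)[..., None], (hi - m)[..., None]
        )
        out[..., aux_idx] = clipped
    return out


@dataclass
class WaveformCohort:
    """Waveform-level synthetic cohort with its ground truth."""

    subjects: pd.DataFrame
    #: subject_id -> {(joint, plane) -> (n_strides, 100) array}
    cycles: dict[str, dict[tuple[str, str], np.ndarray]]
    #: per-subject intended discrete values (group mean + subject effect)
    intended: pd.DataFrame  # n x 112, canonical columns
    #: per-subject realized stride-averaged discrete values from the knots
    realized: pd.DataFrame  # n x 112
    effect_table: dict


def generate_waveform_cohort(spec: CohortSpec) -> WaveformCohort:
    """Generate per-subject gait cycles with injected group effects.

    Returns the cycles plus two ground-truth tables: the *intended*
    per-subject discrete values (group mean + between-subject effect, the
    quantity whose group statistics equal the injected means/SDs) and the
    *realized* stride-averaged values actually present in the cycles
    (identical up to stride noise and rare control-point crossings).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    cohort_ss, *_ = root.spawn(1)
    subjects = _subject_table(spec, np.random.default_rng(cohort_ss))
    subject_seeds = root.spawn(len(subjects))

    n_str = spec.strides_per_subject
    grid = np.arange(1, 101)
    cycles: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    intended_rows, realized_rows = {}, {}

    for (sid, meta), sseed in zip(subjects.iterrows(), subject_seeds):
        rng = np.random.default_rng(sseed)
        per_wave: dict[tuple[str, str], np.ndarray] = {}
        intended: dict[str, float] = {}
        realized: dict[str, float] = {}
        for waveform in WAVEFORMS:
            joint, plane = waveform
            template = WAVEFORM_TEMPLATES[waveform]
            points = np.array([pt for pt, _, _ in template])
            roles = [role for _, role, _ in template]
            means, sds, aux = _knot_arrays(spec, meta["group"], waveform)
            subj_vals = means + rng.normal(size=means.size) * sds
            stride_vals = subj_vals + rng.normal(size=(n_str, means.size)) * spec.stride_noise_sd
            stride_vals = _clip_aux(stride_vals, points, aux)

            interp = PchipInterpolator(points, stride_vals, axis=1, extrapolate=False)
            per_wave[waveform] = interp(grid)

            # ground truth
            stance_m, swing_m = points <= 60, points >= 61
            td = stride_vals[:, points == 1][:, 0]
            to = stride_vals[:, points == 60][:, 0]
            smax = stride_vals[:, stance_m].max(axis=1)
            smin = stride_vals[:, stance_m].min(axis=1)
            wmax = stride_vals[:, swing_m].max(axis=1)
            wmin = stride_vals[:, swing_m].min(axis=1)
            real = {
                "touchdown": td.mean(), "stance_max": smax.mean(),
                "stance_min": smin.mean(), "toeoff": to.mean(),
                "swing_max": wmax.mean(), "swing_min": wmin.mean(),
                "rom_stance": (smax - smin).mean(), "rom_swing": (wmax - wmin).mean(),
            }
            intent = {role: subj_vals[i] for i, role in enumerate(roles) if role != "aux"}
            intent["rom_stance"] = intent["stance_max"] - intent["stance_min"]
            intent["rom_swing"] = intent["swing_max"] - intent["swing_min"]
            for var in real:
                realized[f"{joint}_{plane}_{var}"] = real[var]
                intended[f"{joint}_{plane}_{var}"] = float(intent[var])
        cycles[sid] = per_wave
        intended_rows[sid] = intended
        realized_rows[sid] = realized

    intended_df = pd.DataFrame.from_dict(intended_rows, orient="index")[
        list(FEATURE_COLUMN_NAMES)
    ]
    realized_df = pd.DataFrame.from_dict(realized_rows, orient="index")[
        list(FEATURE_COLUMN_NAMES)
    ]
    intended_df.index.name = realized_df.index.name = "subject_id"
    return WaveformCohort(
        subjects=subjects,
        cycles=cycles,
        intended=intended_df,
        realized=realized_df,
        effect_table=copy.deepcopy(spec.effect_table),
    )


# ---------------------------------------------------------------------------
# marker-level generator
# ---------------------------------------------------------------------------

#: Static standing pose, right side (left side mirrors x). Lab frame:
#: X to the subject's right, Y anterior, Z up; mm.
_STATIC_RIGHT: dict[str, tuple[float, float, float]] = {
    "R_GTRO": (160, 0, 880),
    "R_KNEE_MED": (40, 0, 470), "R_KNEE_LAT": (140, 0, 470),
    "R_MAL_MED": (50, 0, 70), "R_MAL_LAT": (130, 0, 70),
    "R_MT1": (55, 140, 30), "R_MT5": (125, 130, 30),
    "R_TOE": (90, 175, 30),
    "R_HEEL_SUP": (90, -60, 80), "R_HEEL_MED": (65, -55, 35),
    "R_HEEL_LAT": (115, -55, 35),
    "R_TH_1": (150, 30, 700), "R_TH_2": (150, -30, 660),
    "R_TH_3": (140, 25, 610), "R_TH_4": (145, -20, 560),
    "R_SH_1": (135, 25, 350), "R_SH_2": (135, -25, 310),
    "R_SH_3": (125, 20, 260), "R_SH_4": (130, -15, 210),
}

_STATIC_PELVIS = {
    "PELV_1": (0, -150, 980),
    "PELV_2": (60, -140, 940),
    "PELV_3": (-60, -140, 940),
}

#: Sign applied to a template curve when it drives the forward-kinematic
#: chain (knee flexion bends the shank posteriorly).
_FK_SIGN = {("knee", "sagittal"): -1.0}

_HIP_HALF_WIDTH = 90.0
_HIP_HEIGHT = 880.0
_THIGH_LEN = 410.0
_SHANK_LEN = 400.0


def static_marker_set() -> dict[str, np.ndarray]:
    """All static-trial marker positions (both sides + pelvis cluster)."""
    out = {k: np.array(v, dtype=float) for k, v in _STATIC_PELVIS.items()}
    for name, pos in _STATIC_RIGHT.items():
        p = np.array(pos, dtype=float)
        out[name] = p
        out["L" + name[1:]] = p * np.array([-1.0, 1.0, 1.0])
    return out


def _grid_of_phase(phi: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Map cycle phase in [0,1) onto a continuous grid position in [1, 101):
    1..60 over stance, 60..101 over swing, with 101 identified with the next
    cycle's point 1 so periodic evaluation is seamless."""
    phi = np.mod(phi, 1.0)
    g = np.where(
        phi < stance_fraction,
        1.0 + 59.0 * (phi / stance_fraction),
        60.0 + 41.0 * ((phi - stance_fraction) / (1.0 - stance_fraction)),
    )
    return g


def _phase_of_grid(pt: float, stance_fraction: float) -> float:
    if pt <= 60:
        return stance_fraction * (pt - 1.0) / 59.0
    return stance_fraction + (1.0 - stance_fraction) * (pt - 60.0) / 41.0


def _periodic_template_spline(waveform: tuple[str, str]) -> CubicSpline:
    """Smooth periodic base curve through the waveform's control points,
    parameterized by grid position 1..101 (101 wraps to 1).

    A shape-only control point at 100 is dropped so the wrap into the next
    touchdown spans several grid units; a one-unit wrap segment would put an
    implausibly steep transient right at heel strike."""
    template = WAVEFORM_TEMPLATES[waveform]
    knots = [(pt, v) for pt, role, v in template if not (pt == 100 and role == "aux")]
    x = np.array([pt for pt, _ in knots], dtype=float)
    y = np.array([v for _, v in knots], dtype=float)
    x = np.append(x, 101.0)
    y = np.append(y, y[0])
    return CubicSpline(x, y, bc_type="periodic")


def _circular_bump(phi: np.ndarray, centre: float, half_width: float) -> np.ndarray:
    """Cosine-squared bump of unit height on the circle [0, 1)."""
    d = np.abs(np.mod(phi - centre + 0.5, 1.0) - 0.5)
    return np.where(d < half_width, np.cos(0.5 * np.pi * d / half_width) ** 2, 0.0)


_DRIVEN_JOINTS = ("pelvis", "hip", "knee", "ankle")
_BUMP_HALF_WIDTH = 0.12  # cycle fraction; wide enough to survive 10 Hz filtering


def _driven_curves(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> dict[tuple[str, str], "np.vectorize"]:
    """Per-waveform callables angle(phase) for one subject, including the
    subject's whole-curve offset and phase-localized injected effects."""
    curves = {}
    for waveform in WAVEFORMS:
        joint, plane = waveform
        if joint not in _DRIVEN_JOINTS:
            continue
        spline = _periodic_template_spline(waveform)
        offset = rng.normal(0.0, spec.default_subject_sd)
        bumps: list[tuple[float, float]] = []
        template = WAVEFORM_TEMPLATES[waveform]
        for pt, role, base in template:
            entry = spec.effect_table.get((joint, plane, role))
            if entry is None or group not in entry:
                continue
            mean, sd = entry[group]
            target = mean + rng.normal(0.0, sd)
            delta = target - base - offset
            bumps.append((_phase_of_grid(pt, spec.stance_fraction), delta))
        sign = _FK_SIGN.get(waveform, 1.0)

        def make(spline=spline, offset=offset, bumps=tuple(bumps), sign=sign):
            def f(phi: np.ndarray) -> np.ndarray:
                g = _grid_of_phase(phi, 0.6)  # template grid is fixed 60/40
                val = spline(g) + offset
                for centre, delta in bumps:
                    val = val + delta * _circular_bump(np.mod(phi, 1.0), centre, _BUMP_HALF_WIDTH)
                return sign * val
            return f

        curves[waveform] = make()
    return curves


def _chain_poses(
    curves: dict, phi_r: np.ndarray, spec: CohortSpec
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Forward kinematics: per-segment (rotation series, origin series)."""
    n = phi_r.size
    phases = {"right": phi_r, "left": np.mod(phi_r + 0.5, 1.0)}

    def ang(joint: str, phi: np.ndarray, mirror: float):
        sag = curves[(joint, "sagittal")](phi)
        fro = mirror * curves[(joint, "frontal")](phi)
        tra = mirror * curves[(joint, "transverse")](phi)
        return sag, fro, tra

    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sway = 10.0 * np.sin(2 * np.pi * phi_r)
    bob = 15.0 * np.sin(4 * np.pi * phi_r)
    pel_origin = np.column_stack(
        [sway, np.zeros(n), _HIP_HEIGHT + bob]
    )
    R_pelvis = kin.cardan_compose(*ang("pelvis", phi_r, 1.0))
    poses["pelvis"] = (R_pelvis, pel_origin)

    static = static_marker_set()
    for side, sigma in (("right", 1.0), ("left", -1.0)):
        phi = phases[side]
        hip_local = np.array([sigma * _HIP_HALF_WIDTH, 0.0, 0.0])
        hip_c = pel_origin + R_pelvis @ hip_local
        R_thigh = np.einsum(
            "nij,njk->nik", R_pelvis, kin.cardan_compose(*ang("hip", phi, sigma))
        )
        knee_c = hip_c + R_thigh @ np.array([0.0, 0.0, -_THIGH_LEN])
        R_shank = np.einsum(
            "nij,njk->nik", R_thigh, kin.cardan_compose(*ang("knee", phi, sigma))
        )
        ankle_c = knee_c + R_shank @ np.array([0.0, 0.0, -_SHANK_LEN])
        R_foot = np.einsum(
            "nij,njk->nik", R_shank, kin.cardan_compose(*ang("ankle", phi, sigma))
        )
        prefix = "R" if side == "right" else "L"
        heel_static = np.mean(
            [static[f"{prefix}_HEEL_{k}"] for k in ("SUP", "MED", "LAT")], axis=0
        )
        ankle_static = np.array([sigma * 90.0, 0.0, 70.0])
        foot_origin = ankle_c + R_foot @ (heel_static - ankle_static)
        poses[f"{side}_thigh"] = (R_thigh, knee_c)
        poses[f"{side}_shank"] = (R_shank, ankle_c)
        poses[f"{side}_foot"] = (R_foot, foot_origin)
    return poses


_SEGMENT_ORIGINS_STATIC = {
    "pelvis": np.array([0.0, 0.0, _HIP_HEIGHT]),
    "right_thigh": np.array([90.0, 0.0, 470.0]),
    "left_thigh": np.array([-90.0, 0.0, 470.0]),
    "right_shank": np.array([90.0, 0.0, 70.0]),
    "left_shank": np.array([-90.0, 0.0, 70.0]),
    "right_foot": np.array([90.0, -170.0 / 3.0, 50.0]),
    "left_foot": np.array([-90.0, -170.0 / 3.0, 50.0]),
}


def _marker_segment(name: str) -> str | None:
    """Walking-trial marker -> segment carrying it (clusters + toe)."""
    if name.startswith("PELV"):
        return "pelvis"
    side = "right" if name.startswith("R_") else "left"
    base = name[2:]
    if base.startswith("TH_"):
        return f"{side}_thigh"
    if base.startswith("SH_"):
        return f"{side}_shank"
    if base.startswith("HEEL") or base == "TOE":
        return f"{side}_foot"
    return None  # anatomical markers are removed for walking


@dataclass
class MarkerGroundTruth:
    """Ground truth for one marker-level subject."""

    heel_strikes: dict[str, np.ndarray]  # side -> frames
    toe_offs: dict[str, np.ndarray]
    #: side -> {(joint, plane) -> per-frame driven/derived angle series}
    angle_curves: dict[str, dict[tuple[str, str], np.ndarray]]
    poses: dict[str, tuple[np.ndarray, np.ndarray]]
    #: side -> {(joint, plane) -> {variable -> stride-averaged value}}
    discrete: dict[str, dict[tuple[str, str], dict[str, float]]]
    frames_per_stride: int


def generate_marker_cohort(
    spec: CohortSpec,
    settle_strides: int = 2,
) -> tuple[list[SubjectRecording], dict[str, MarkerGroundTruth]]:
    """Generate marker-level recordings for a cohort.

    Each subject's walking trial covers ``settle_strides + strides_per_subject
    + 2`` stride cycles at a speed-dependent cadence. Ground-truth events are
    the per-cycle extrema of the noiseless heel/toe marker anterior
    coordinate; ground-truth discrete variables come from the generator's own
    driven angle curves segmented at those events.
    """
    spec.validate()
    root = np.random.SeedSequence([spec.seed, 9021])
    cohort_ss, *_ = root.spawn(1)
    subjects = _subject_table(spec, np.random.default_rng(cohort_ss))
    subject_seeds = root.spawn(len(subjects))
    static = static_marker_set()

    recordings: list[SubjectRecording] = []
    truths: dict[str, MarkerGroundTruth] = {}
    for (sid, meta), sseed in zip(subjects.iterrows(), subject_seeds):
        rng = np.random.default_rng(sseed)
        speed = float(meta["speed"])
        stride_time = float(np.clip(1.35 - 0.25 * speed, 0.9, 1.2))
        spf = int(round(spec.sampling_rate * stride_time))  # frames per stride
        n_cycles = settle_strides + spec.strides_per_subject + 3
        n_frames = n_cycles * spf + 1
        t = np.arange(n_frames)
        phi_r = (t / spf) % 1.0

        curves = _driven_curves(spec, meta["group"], rng)
        poses = _chain_poses(curves, t / spf, spec)

        # rigid marker attachment
        traj: dict[str, MarkerTrajectory] = {}
        for name in static:
            seg = _marker_segment(name)
            if seg is None:
                continue
            R, origin = poses[seg]
            local = static[name] - _SEGMENT_ORIGINS_STATIC[seg]
            pos = origin + np.einsum("nij,j->ni", R, local)
            noisy = pos + rng.normal(0.0, spec.marker_noise_sd_mm, pos.shape)
            traj[name] = MarkerTrajectory(name, seg, noisy, spec.sampling_rate)

        # ground-truth events from the noiseless construction
        hs, to = {}, {}
        for side, prefix, phase_shift in (("right", "R", 0.0), ("left", "L", 0.5)):
            seg = f"{side}_foot"
            R, origin = poses[seg]
            heel_ap = (
                origin + np.einsum("nij,j->ni", R, static[f"{prefix}_HEEL_SUP"] - _SEGMENT_ORIGINS_STATIC[seg])
            )[:, 1]
            toe_ap = (
                origin + np.einsum("nij,j->ni", R, static[f"{prefix}_TOE"] - _SEGMENT_ORIGINS_STATIC[seg])
            )[:, 1]
            hs_frames, to_frames = [], []
            for k in range(n_cycles):
                c_hs = (k + phase_shift) * spf
                lo, hi = int(c_hs - 0.5 * spf), int(c_hs + 0.5 * spf)
                if lo >= 0 and hi < n_frames:
                    hs_frames.append(lo + int(np.argmax(heel_ap[lo:hi])))
                c_to = (k + phase_shift + spec.stance_fraction) * spf
                lo, hi = int(c_to - 0.5 * spf), int(c_to + 0.5 * spf)
                if lo >= 0 and hi < n_frames:
                    to_frames.append(lo + int(np.argmin(toe_ap[lo:hi])))
            ev = pair_events(np.array(hs_frames), np.array(to_frames))
            hs[side] = ev.heel_strikes
            to[side] = ev.toe_offs

        # ground-truth angle series and discrete variables per side
        angle_curves: dict[str, dict[tuple[str, str], np.ndarray]] = {}
        discrete: dict[str, dict[tuple[str, str], dict[str, float]]] = {}
        for side, sigma in (("right", 1.0), ("left", -1.0)):
            phi = phi_r if side == "right" else np.mod(phi_r + 0.5, 1.0)
            per: dict[tuple[str, str], np.ndarray] = {}
            for waveform, f in curves.items():
                p = phi_r if waveform[0] == "pelvis" else phi
                # ground truth is what the kinematic chain realizes, i.e.
                # the driver including any forward-kinematic sign
                series = f(p)
                if waveform[0] == "pelvis" and side == "left" and waveform[1] != "sagittal":
                    series = -series
                per[waveform] = series
            # foot segment angles: decompose the composed foot rotation
            Rf = poses[f"{side}_foot"][0]
            sag, fro, tra, _ = kin.cardan_decompose(Rf)
            if side == "left":
                tra = -tra
            per[("foot", "sagittal")] = sag
            per[("foot", "transverse")] = tra
            angle_curves[side] = per

            events = GaitEvents(hs[side], to[side])
            disc: dict[tuple[str, str], dict[str, float]] = {}
            for waveform, series in per.items():
                cyc = segment_normalize(
                    series, events, strides=spec.strides_per_subject,
                    settle_strides=settle_strides,
                )
                disc[waveform] = average_strides(
                    [extract_discrete(c) for c in cyc], spec.strides_per_subject
                )
            discrete[side] = disc

        segment_poses = {
            k: v for k, v in poses.items() if not k.startswith("_")
        }
        recordings.append(
            SubjectRecording(
                subject_id=sid,
                sex=meta["sex"],
                status=meta["status"],
                affected_side=meta["affected_side"],
                walking_speed=speed,
                static_markers={k: v.copy() for k, v in static.items()},
                walking_markers=traj,
                sampling_rate=spec.sampling_rate,
                metadata={"bilateral": bool(meta["bilateral"]), "group": meta["group"]},
            )
        )
        truths[sid] = MarkerGroundTruth(
            heel_strikes=hs,
            toe_offs=to,
            angle_curves=angle_curves,
            poses=segment_poses,
            discrete=discrete,
            frames_per_stride=spf,
        )
    return recordings, truths
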