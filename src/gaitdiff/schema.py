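"""Core vocabulary and containers of the analysis.

The analysis describes lower-limb walking kinematics by 14 joint/segment
angle waveforms — ankle, knee and hip joints plus the pelvis segment in all
three anatomical planes, and the foot segment in the sagittal and transverse
planes only (foot motion is referenced to the lab, where a frontal-plane
series is not defined by the marker set). Each waveform is reduced to eight
discrete variables, giving the canonical 112-column feature vector per
subject.

Every gait cycle is time-normalized to exactly 100 points: points 1-60 are
the stance phase (heel strike to toe-off) and points 61-100 the swing phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

JOINTS = ("ankle", "knee", "hip", "pelvis", "foot")
PLANES = ("sagittal", "frontal", "transverse")

#: The 14 (joint, plane) waveforms, joint-major, plane order sagittal,
#: frontal, transverse; the foot carries no frontal-plane series.
WAVEFORMS: tuple[tuple[str, str], ...] = tuple(
    (joint, plane)
    for joint in JOINTS
    for plane in PLANES
    if not (joint == "foot" and plane == "frontal")
)

#: The eight discrete variables extracted per waveform, in canonical order.
VARIABLES = (
    "touchdown",
    "stance_max",
    "stance_min",
    "toeoff",
    "swing_max",
    "swing_min",
    "rom_stance",
    "rom_swing",
)

#: Variables that are direct point values on the 100-point cycle (as opposed
#: to the two derived ranges of motion).
POINT_VARIABLES = VARIABLES[:6]

#: Canonical 112 feature columns: joint-major, plane-minor, variable-innermost.
FEATURE_COLUMNS: tuple[tuple[str, str, str], ...] = tuple(
    (joint, plane, var) for joint, plane in WAVEFORMS for var in VARIABLES
)

N_FEATURES = len(FEATURE_COLUMNS)  # 112
assert N_FEATURES == 112

CYCLE_POINTS = 100
STANCE_POINTS = 60
SWING_POINTS = 40


def column_name(joint: str, plane: str, var: str) -> str:
    return f"{joint}_{plane}_{var}"


FEATURE_COLUMN_NAMES = tuple(column_name(*c) for c in FEATURE_COLUMNS)


@dataclass
class MarkerTrajectory:
    """A named 3D point series in lab coordinates (mm) at a fixed rate."""

    marker_id: str
    segment: str
    positions: np.ndarray  # (n_frames, 3), mm
    sampling_rate: float = 120.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_frames, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite marker coordinates")


@dataclass
class SegmentPose:
    """Per-frame rigid pose of one segment (segment -> lab)."""

    rotations: np.ndarray  # (n_frames, 3, 3)
    translations: np.ndarray  # (n_frames, 3), mm
    residuals: np.ndarray  # (n_frames,), RMS marker fit error, mm

    def __len__(self) -> int:
        return self.rotations.shape[0]


@dataclass
class JointAngleWaveform:
    """One joint/plane angle series in degrees, per raw frame."""

    joint: str
    plane: str
    angles: np.ndarray
    gimbal_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.joint == "foot" and self.plane == "frontal":
            raise ValueError("the foot segment carries no frontal-plane series")
        self.angles = np.asarray(self.angles, dtype=float)


@dataclass
class GaitEvents:
    """Heel-strike and toe-off frame indices; toe-offs alternate strictly
    between consecutive heel strikes."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)


@dataclass
class GaitCycle:
    """One time-normalized 100-point cycle (60 stance + 40 swing points)."""

    waveform: np.ndarray  # (100,)
    stride: int = 0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.shape != (CYCLE_POINTS,):
            raise ValueError("a gait cycle has exactly 100 points")

    @property
    def stance(self) -> np.ndarray:
        return self.waveform[:STANCE_POINTS]

    @property
    def swing(self) -> np.ndarray:
        return self.waveform[STANCE_POINTS:]


@dataclass
class SubjectRecording:
    """One subject's static + walking marker trials with metadata."""

    subject_id: str
    sex: str  # "male" | "female"
    status: str  # "OA" | "control"
    affected_side: str | None  # "left" | "right" | None for controls
    walking_speed: float  # m/s
    static_markers: dict[str, np.ndarray]  # marker -> (3,) mm
    walking_markers: dict[str, MarkerTrajectory]
    sampling_rate: float = 120.0
    metadata: dict = field(default_factory=dict)
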