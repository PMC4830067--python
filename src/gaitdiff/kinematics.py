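"""Rigid-body kinematics: marker clusters to segment poses to joint angles.

The processing chain mirrors standard clinical gait analysis:

1. a one-second static trial with 14 anatomical landmarks (greater
   trochanters, medial/lateral knee joint lines, malleoli, 1st/5th
   metatarsal heads) plus technical marker clusters defines, per segment, an
   anatomical coordinate frame and the fixed mapping from the technical
   cluster to that frame;
2. during walking only the technical clusters are tracked; each segment's
   pose per frame is the least-squares rigid transform (rotation +
   translation) fitted by singular value decomposition;
3. joint angles are Cardan angles of the distal anatomical frame relative to
   the proximal one, in the joint-coordinate-system sequence
   flexion/extension (about the proximal mediolateral axis) ->
   ab/adduction (floating axis) -> internal/external rotation (about the
   distal longitudinal axis). Pelvis and foot angles are taken relative to
   the lab frame.

Anatomical frames use X pointing to the subject's right (mediolateral),
Y anterior, Z up/longitudinal; for the left side the frontal- and
transverse-plane angles are mirrored so that adduction and internal rotation
are positive on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfigurationError, MissingMarkerError
from .schema import JointAngleWaveform, SegmentPose

GIMBAL_MARGIN_DEG = 0.5

#: Technical cluster marker names per segment.
CLUSTER_MARKERS: dict[str, tuple[str, ...]] = {
    "pelvis": ("PELV_1", "PELV_2", "PELV_3"),
    "left_thigh": ("L_TH_1", "L_TH_2", "L_TH_3", "L_TH_4"),
    "right_thigh": ("R_TH_1", "R_TH_2", "R_TH_3", "R_TH_4"),
    "left_shank": ("L_SH_1", "L_SH_2", "L_SH_3", "L_SH_4"),
    "right_shank": ("R_SH_1", "R_SH_2", "R_SH_3", "R_SH_4"),
    "left_foot": ("L_HEEL_SUP", "L_HEEL_MED", "L_HEEL_LAT"),
    "right_foot": ("R_HEEL_SUP", "R_HEEL_MED", "R_HEEL_LAT"),
}

#: The 14 anatomical landmark markers (static trial only).
ANATOMICAL_MARKERS: tuple[str, ...] = tuple(
    f"{s}_{m}"
    for s in ("L", "R")
    for m in ("GTRO", "KNEE_MED", "KNEE_LAT", "MAL_MED", "MAL_LAT", "MT1", "MT5")
)

#: Default medial offset (mm) from the greater trochanter marker to the hip
#: joint centre, along the pelvis mediolateral axis. The marker set has no
#: pelvic landmarks for a regression-based hip centre, so a fixed offset is
#: used; the value is a conventional adult approximation, not measured here.
HIP_CENTRE_MEDIAL_OFFSET_MM = 70.0

LAB_UP = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# rigid transform fitting (least-squares SVD solution)
# ---------------------------------------------------------------------------

def fit_rigid_batch(
    reference: np.ndarray, current: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid transforms mapping one reference marker
    configuration onto a batch of observed configurations.

    Parameters
    ----------
    reference
        (k, 3) reference marker positions (k >= 3, non-collinear).
    current
        (..., k, 3) observed positions; leading axes are batch axes.

    Returns
    -------
    rotations (..., 3, 3), translations (..., 3), residuals (...,) — the RMS
    marker fit error in the units of the input.
    """
    ref = np.asarray(reference, dtype=float)
    cur = np.asarray(current, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise DegenerateConfigurationError("reference must be (k, 3)")
    k = ref.shape[0]
    if k < 3:
        raise DegenerateConfigurationError(
            f"rigid fitting needs >=3 markers, got {k}"
        )
    if cur.shape[-2:] != (k, 3):
        raise DegenerateConfigurationError(
            "current marker block must match the reference marker count"
        )
    ref_c = ref - ref.mean(axis=0)
    # collinearity: the centred reference must span a plane
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("reference markers are collinear")

    cur_mean = cur.mean(axis=-2, keepdims=True)
    cur_c = cur - cur_mean
    # cross-dispersion H = sum_i (cur_i - cbar)(ref_i - rbar)^T
    H = np.einsum("...ki,kj->...ij", cur_c, ref_c)
    U, _, Vt = np.linalg.svd(H)
    # correct a reflection by flipping the smallest singular direction
    det = np.linalg.det(np.einsum("...ij,...jk->...ik", U, Vt))
    D = np.zeros(det.shape + (3, 3))
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = det
    R = np.einsum("...ij,...jk,...kl->...il", U, D, Vt)
    t = cur_mean[..., 0, :] - np.einsum("...ij,j->...i", R, ref.mean(axis=0))
    fitted = np.einsum("...ij,kj->...ki", R, ref_c)
    resid = np.sqrt(np.mean(np.sum((cur_c - fitted) ** 2, axis=-1), axis=-1))
    return R, t, resid


def fit_rigid_transform(
    reference: np.ndarray, current: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Single-frame rigid fit; see :func:`fit_rigid_batch`."""
    R, t, resid = fit_rigid_batch(reference, np.asarray(current, dtype=float))
    return R, t, float(resid)


# ---------------------------------------------------------------------------
# Cardan / joint-coordinate-system angles
# ---------------------------------------------------------------------------

def cardan_compose(sagittal: float, frontal: float, transverse: float) -> np.ndarray:
    """Rotation matrix from Cardan angles (degrees) in the JCS sequence:
    about X (flexion), then the rotated Y (ab/adduction, floating axis),
    then the twice-rotated Z (axial rotation). Accepts arrays."""
    a, b, c = (np.deg2rad(np.asarray(v, dtype=float)) for v in (sagittal, frontal, transverse))
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    shape = np.broadcast(ca, cb, cc).shape
    R = np.empty(shape + (3, 3))
    R[..., 0, 0] = cb * cc
    R[..., 0, 1] = -cb * sc
    R[..., 0, 2] = sb
    R[..., 1, 0] = ca * sc + sa * sb * cc
    R[..., 1, 1] = ca * cc - sa * sb * sc
    R[..., 1, 2] = -sa * cb
    R[..., 2, 0] = sa * sc - ca * sb * cc
    R[..., 2, 1] = sa * cc + ca * sb * sc
    R[..., 2, 2] = ca * cb
    return R


def cardan_decompose(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`cardan_compose`. Returns (sagittal, frontal,
    transverse) in degrees plus a boolean gimbal-proximity flag per frame
    (floating axis within 0.5 deg of alignment, i.e. |frontal| within
    0.5 deg of 90). Angles are still returned for flagged frames."""
    R = np.asarray(R, dtype=float)
    sb = np.clip(R[..., 0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    a = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    c = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    flag = np.abs(np.rad2deg(np.abs(b)) - 90.0) < GIMBAL_MARGIN_DEG
    return np.rad2deg(a), np.rad2deg(b), np.rad2deg(c), flag


def joint_angles(
    proximal: SegmentPose | None,
    distal: SegmentPose,
    joint: str,
    side: str = "right",
) -> dict[str, JointAngleWaveform]:
    """Three-plane joint angles of the distal segment relative to the
    proximal one (degrees). ``proximal=None`` references the lab frame
    (pelvis and foot segment angles). Left-side frontal and transverse
    angles are mirrored so adduction/internal rotation read positive on both
    sides; the foot yields sagittal and transverse series only."""
    Rd = distal.rotations
    if proximal is None:
        Rrel = Rd
    else:
        Rp = proximal.rotations
        if Rp.shape != Rd.shape:
            raise ValueError("proximal and distal pose series differ in length")
        Rrel = np.einsum("...ji,...jk->...ik", Rp, Rd)  # Rp^T Rd
    sag, fro, tra, flag = cardan_decompose(Rrel)
    if side == "left":
        fro = -fro
        tra = -tra
    out = {"sagittal": JointAngleWaveform(joint, "sagittal", sag, flag)}
    if joint != "foot":
        out["frontal"] = JointAngleWaveform(joint, "frontal", fro, flag)
    out["transverse"] = JointAngleWaveform(joint, "transverse", tra, flag)
    return out


# ---------------------------------------------------------------------------
# static-trial calibration
# ---------------------------------------------------------------------------

@dataclass
class SegmentCalibration:
    """One segment's anatomical frame at the static trial plus the fixed
    technical-cluster mapping used to track it during walking."""

    segment: str
    rotation: np.ndarray  # anatomical axes as columns, in lab coordinates
    origin: np.ndarray  # mm, lab
    cluster_markers: tuple[str, ...]
    cluster_reference: np.ndarray  # (k, 3) cluster positions at static, lab
    joint_centres: dict[str, np.ndarray]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateConfigurationError("zero-length axis vector")
    return v / n


def _frame_from_z_x(z_axis: np.ndarray, x_hint: np.ndarray) -> np.ndarray:
    """Right-handed frame with exact Z (longitudinal) and X as close as
    possible to the mediolateral hint."""
    z = _unit(z_axis)
    y = _unit(np.cross(z, x_hint))
    x = np.cross(y, z)
    return np.column_stack([x, y, z])


def _require(static: dict[str, np.ndarray], names: tuple[str, ...]) -> np.ndarray:
    missing = [m for m in names if m not in static]
    if missing:
        raise MissingMarkerError(f"missing marker(s): {', '.join(missing)}")
    return np.array([static[m] for m in names], dtype=float)


def calibrate_segments(
    static_markers: dict[str, np.ndarray],
    hip_offset_mm: float = HIP_CENTRE_MEDIAL_OFFSET_MM,
) -> dict[str, SegmentCalibration]:
    """Build per-segment anatomical frames and cluster mappings from one
    static frame containing all anatomical and technical markers.

    Joint centres: knee = midpoint of the medial/lateral joint-line markers;
    ankle = midpoint of the malleoli; hip = greater trochanter displaced
    medially (toward the contralateral trochanter) by ``hip_offset_mm``.
    Longitudinal axes join the segment's joint centres; mediolateral axes
    come from the paired anatomical markers; the foot frame uses the lab
    vertical.
    """
    _require(static_markers, ANATOMICAL_MARKERS)
    for seg, names in CLUSTER_MARKERS.items():
        _require(static_markers, names)

    s = {k: np.asarray(v, dtype=float) for k, v in static_markers.items()}
    centres: dict[str, np.ndarray] = {}
    for side in ("L", "R"):
        centres[f"{side}_knee"] = 0.5 * (s[f"{side}_KNEE_MED"] + s[f"{side}_KNEE_LAT"])
        centres[f"{side}_ankle"] = 0.5 * (s[f"{side}_MAL_MED"] + s[f"{side}_MAL_LAT"])
    for side, other in (("L", "R"), ("R", "L")):
        medial = _unit(s[f"{other}_GTRO"] - s[f"{side}_GTRO"])
        centres[f"{side}_hip"] = s[f"{side}_GTRO"] + hip_offset_mm * medial

    out: dict[str, SegmentCalibration] = {}

    def add(segment: str, rotation: np.ndarray, origin: np.ndarray,
            joint_centres: dict[str, np.ndarray]) -> None:
        names = CLUSTER_MARKERS[segment]
        ref = np.array([s[m] for m in names])
        out[segment] = SegmentCalibration(
            segment=segment,
            rotation=rotation,
            origin=np.asarray(origin, dtype=float),
            cluster_markers=names,
            cluster_reference=ref,
            joint_centres={k: v.copy() for k, v in joint_centres.items()},
        )

    # pelvis: X right hip -> contains both hip centres; Z vertical-projected
    x_pel = _unit(centres["R_hip"] - centres["L_hip"])
    z_pel = _unit(LAB_UP - np.dot(LAB_UP, x_pel) * x_pel)
    y_pel = np.cross(z_pel, x_pel)
    add(
        "pelvis",
        np.column_stack([x_pel, y_pel, z_pel]),
        0.5 * (centres["L_hip"] + centres["R_hip"]),
        {"L_hip": centres["L_hip"], "R_hip": centres["R_hip"]},
    )

    for side in ("L", "R"):
        pre = "left" if side == "L" else "right"
        # X hint points to the subject's right for both sides
        if side == "R":
            ml_knee = s["R_KNEE_LAT"] - s["R_KNEE_MED"]
            ml_ankle = s["R_MAL_LAT"] - s["R_MAL_MED"]
            ml_foot = s["R_MT5"] - s["R_MT1"]
        else:
            ml_knee = s["L_KNEE_MED"] - s["L_KNEE_LAT"]
            ml_ankle = s["L_MAL_MED"] - s["L_MAL_LAT"]
            ml_foot = s["L_MT1"] - s["L_MT5"]

        add(
            f"{pre}_thigh",
            _frame_from_z_x(centres[f"{side}_hip"] - centres[f"{side}_knee"], ml_knee),
            centres[f"{side}_knee"],
            {"hip": centres[f"{side}_hip"], "knee": centres[f"{side}_knee"]},
        )
        add(
            f"{pre}_shank",
            _frame_from_z_x(centres[f"{side}_knee"] - centres[f"{side}_ankle"], ml_ankle),
            centres[f"{side}_ankle"],
            {"knee": centres[f"{side}_knee"], "ankle": centres[f"{side}_ankle"]},
        )
        heel = np.mean(
            [s[m] for m in CLUSTER_MARKERS[f"{pre}_foot"]], axis=0
        )
        mt_mid = 0.5 * (s[f"{side}_MT1"] + s[f"{side}_MT5"])
        y_foot = mt_mid - heel
        y_foot = _unit(y_foot - np.dot(y_foot, LAB_UP) * LAB_UP)
        x_foot = _unit(np.cross(y_foot, LAB_UP))
        if np.dot(x_foot, ml_foot) < 0:
            # keep X to the subject's right even if marker geometry is mirrored
            x_foot = -x_foot
            y_foot = np.cross(LAB_UP, x_foot)
        add(
            f"{pre}_foot",
            np.column_stack([x_foot, y_foot, LAB_UP.copy()]),
            heel,
            {"ankle": centres[f"{side}_ankle"]},
        )
    return out


def track_segment(
    calibration: SegmentCalibration,
    marker_positions: dict[str, np.ndarray],
) -> SegmentPose:
    """Pose series of one segment from its technical cluster.

    ``marker_positions`` maps marker name to an (n_frames, 3) array (already
    filtered). The returned rotations map anatomical-frame coordinates to
    lab coordinates; translations locate the anatomical origin.
    """
    missing = [m for m in calibration.cluster_markers if m not in marker_positions]
    if missing:
        raise MissingMarkerError(f"missing marker(s): {', '.join(missing)}")
    cur = np.stack(
        [np.asarray(marker_positions[m], dtype=float) for m in calibration.cluster_markers],
        axis=1,
    )  # (n_frames, k, 3)
    # express the static cluster in the anatomical frame once
    local = (calibration.cluster_reference - calibration.origin) @ calibration.rotation
    R, t, resid = fit_rigid_batch(local, cur)
    return SegmentPose(rotations=R, translations=t, residuals=resid)
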