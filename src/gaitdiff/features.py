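"""Discrete variables per waveform and the n x 112 subject feature matrix.

Eight discrete variables summarize each 100-point gait-cycle waveform:
angle at touchdown (point 1), maximum and minimum peak angles during stance
(points 1-60), angle at toe-off (point 60), maximum and minimum peak angles
during swing (points 61-100), and the stance and swing ranges of motion
(phase max minus phase min). Variables are averaged over ten consecutive
strides and taken from one side per subject: the affected side for
unilateral OA, the recorded most-affected side for bilateral OA, and a
reproducibly random side for controls.

Across the 14 joint/plane waveforms this yields the canonical
112-dimensional row vector per subject; column order is joint-major
(ankle, knee, hip, pelvis, foot), plane-minor (sagittal, frontal,
transverse) and variable-innermost, frozen in
:data:`gaitdiff.schema.FEATURE_COLUMNS`.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .errors import (
    CountMismatchError,
    InvalidCycleError,
    MissingMetadataError,
    MissingWaveformError,
)
from .schema import (
    FEATURE_COLUMN_NAMES,
    GaitCycle,
    STANCE_POINTS,
    SubjectRecording,
    VARIABLES,
    WAVEFORMS,
)


def extract_discrete(cycle: GaitCycle | np.ndarray) -> dict[str, float]:
    """The eight discrete variables of one 100-point cycle, in degrees."""
    w = cycle.waveform if isinstance(cycle, GaitCycle) else np.asarray(cycle, dtype=float)
    if w.shape != (100,):
        raise InvalidCycleError("cycle must have exactly 100 points")
    if not np.all(np.isfinite(w)):
        raise InvalidCycleError("cycle contains non-finite values")
    stance, swing = w[:STANCE_POINTS], w[STANCE_POINTS:]
    out = {
        "touchdown": float(w[0]),
        "stance_max": float(stance.max()),
        "stance_min": float(stance.min()),
        "toeoff": float(w[STANCE_POINTS - 1]),
        "swing_max": float(swing.max()),
        "swing_min": float(swing.min()),
    }
    out["rom_stance"] = out["stance_max"] - out["stance_min"]
    out["rom_swing"] = out["swing_max"] - out["swing_min"]
    return out


def average_strides(per_stride: list[dict[str, float]], strides: int = 10) -> dict[str, float]:
    """Arithmetic mean of per-stride discrete variables over exactly
    ``strides`` strides. ROM is linear in the per-stride extrema, so the
    mean ROM equals mean(max) - mean(min); this is asserted."""
    if len(per_stride) != strides:
        raise CountMismatchError(
            f"expected {strides} per-stride feature sets, got {len(per_stride)}"
        )
    out = {v: float(np.mean([f[v] for f in per_stride])) for v in VARIABLES}
    assert abs(out["rom_stance"] - (out["stance_max"] - out["stance_min"])) < 1e-9
    assert abs(out["rom_swing"] - (out["swing_max"] - out["swing_min"])) < 1e-9
    return out


def select_side(subject: SubjectRecording, seed: int) -> str:
    """Side whose waveforms enter the analysis: affected (or most-affected)
    side for OA subjects, a seeded uniform random side for controls."""
    if subject.status == "OA":
        if subject.affected_side not in ("left", "right"):
            raise MissingMetadataError(
                f"OA subject {subject.subject_id} has no affected-side metadata"
            )
        return subject.affected_side
    digest = zlib.crc32(subject.subject_id.encode("utf-8"))
    rng = np.random.default_rng([seed, digest])
    return "left" if rng.random() < 0.5 else "right"


def assemble_matrix(
    cohort_features: dict[str, dict[tuple[str, str], dict[str, float]]],
    labels: pd.DataFrame | dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Assemble per-subject per-waveform discrete variables into the
    n x 112 feature matrix.

    Parameters
    ----------
    cohort_features
        subject_id -> {(joint, plane) -> {variable -> value}}.
    labels
        Optional subject_id -> {"sex": ..., "status": ..., "side": ...};
        attached as leading label columns.

    Returns
    -------
    DataFrame indexed by subject with the 112 canonical feature columns
    (plus any label columns first).
    """
    rows = {}
    for sid, per_wave in cohort_features.items():
        row = {}
        for joint, plane in WAVEFORMS:
            if (joint, plane) not in per_wave:
                raise MissingWaveformError(
                    f"subject {sid} is missing the ({joint}, {plane}) waveform"
                )
            feats = per_wave[(joint, plane)]
            for var in VARIABLES:
                if var not in feats:
                    raise MissingWaveformError(
                        f"subject {sid} ({joint}, {plane}) lacks variable {var}"
                    )
                row[f"{joint}_{plane}_{var}"] = feats[var]
        rows[sid] = row
    X = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_COLUMN_NAMES)]
    X.index.name = "subject_id"
    if X.isna().any().any():
        raise MissingWaveformError("feature matrix contains missing values")
    if labels is not None:
        lab = labels if isinstance(labels, pd.DataFrame) else pd.DataFrame.from_dict(labels, orient="index")
        X = lab.loc[X.index].join(X)
    return X
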