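"""End-to-end orchestration: markers or cycles in, statistics and
classification out.

The stages reproduce the study's processing order: low-pass filter marker
trajectories, calibrate segments from the static trial, track segment poses
from technical clusters, compute joint-coordinate-system angles, detect
heel strikes and toe-offs, normalize ten consecutive strides to 100-point
cycles, extract and average the eight discrete variables per waveform,
assemble the n x 112 feature matrix, then run the univariate
(ANOVA + Cohen's d + Holm) and multivariate (effect-size-ranked incremental
linear SVM) analyses per group comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .errors import GaitError
from .events import detect_heel_strikes, detect_toe_offs, pair_events, segment_normalize
from .features import assemble_matrix, average_strides, extract_discrete, select_side
from .filtering import butterworth_lowpass
from .kinematics import calibrate_segments, joint_angles, track_segment
from .schema import SubjectRecording, WAVEFORMS
from .selection import SelectionResult, incremental_selection, run_pc_pathway
from .stats import effect_size_table

_AXES = {"+x": (0, 1.0), "-x": (0, -1.0), "+y": (1, 1.0), "-y": (1, -1.0)}


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the study's settings."""

    anterior_axis: str = "+y"
    marker_map: dict[str, str] | None = None
    filter_cutoff_hz: float = 10.0
    filter_order: int = 2
    sampling_rate_hz: float = 120.0
    strides: int = 10
    settle_strides: int = 2  # not from the study; see docs
    cv_folds: int = 10
    soft_margin: float = 1.0
    significance_p: float = 0.05
    meaningful_d: float = 0.8
    seed: int = 0
    selection_mode: str = "paper-faithful"

    def validate(self) -> None:
        if self.anterior_axis not in _AXES:
            raise GaitError(f"anterior_axis must be one of {sorted(_AXES)}")
        if min(self.filter_cutoff_hz, self.sampling_rate_hz, self.strides,
               self.cv_folds, self.soft_margin) <= 0:
            raise GaitError("numeric pipeline settings must be positive")
        if not (0 < self.significance_p < 1) or self.meaningful_d <= 0:
            raise GaitError("bad significance thresholds")


_SIDE_JOINTS = {
    "hip": ("pelvis", "{side}_thigh"),
    "knee": ("{side}_thigh", "{side}_shank"),
    "ankle": ("{side}_shank", "{side}_foot"),
    "pelvis": (None, "pelvis"),
    "foot": (None, "{side}_foot"),
}


def process_recording(
    recording: SubjectRecording, config: PipelineConfig
) -> dict:
    """One subject: markers -> per-side angles, events, cycles and averaged
    discrete variables. Returns a dict with keys ``side`` (the analysis
    side), ``events`` (per side), ``angles`` (per side), and ``discrete``
    (analysis side only, waveform -> variable -> value)."""
    config.validate()
    axis, sign = _AXES[config.anterior_axis]

    filtered = {
        name: butterworth_lowpass(
            tr.positions, config.filter_cutoff_hz, config.filter_order,
            recording.sampling_rate,
        )
        for name, tr in recording.walking_markers.items()
    }
    calib = calibrate_segments(recording.static_markers)
    poses = {seg: track_segment(calib[seg], filtered) for seg in calib}

    out_events: dict[str, dict[str, np.ndarray]] = {}
    out_angles: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for side, prefix in (("left", "L"), ("right", "R")):
        heel_ap = sign * filtered[f"{prefix}_HEEL_SUP"][:, axis]
        toe_ap = sign * filtered[f"{prefix}_TOE"][:, axis]
        ev = pair_events(detect_heel_strikes(heel_ap), detect_toe_offs(toe_ap))
        out_events[side] = {"heel_strikes": ev.heel_strikes, "toe_offs": ev.toe_offs}

        per: dict[tuple[str, str], np.ndarray] = {}
        for joint, (prox, dist) in _SIDE_JOINTS.items():
            prox_pose = poses[prox.format(side=side)] if prox else None
            dist_pose = poses[dist.format(side=side)]
            waves = joint_angles(prox_pose, dist_pose, joint, side=side)
            for plane, wf in waves.items():
                per[(joint, plane)] = wf.angles
        out_angles[side] = per

    side = select_side(recording, config.seed)
    ev = out_events[side]
    events = pair_events(ev["heel_strikes"], ev["toe_offs"])
    discrete: dict[tuple[str, str], dict[str, float]] = {}
    for waveform in WAVEFORMS:
        cycles = segment_normalize(
            out_angles[side][waveform], events,
            strides=config.strides, settle_strides=config.settle_strides,
        )
        discrete[waveform] = average_strides(
            [extract_discrete(c) for c in cycles], config.strides
        )
    return {
        "side": side,
        "events": out_events,
        "angles": out_angles,
        "discrete": discrete,
    }


def features_from_recordings(
    recordings: list[SubjectRecording], config: PipelineConfig
) -> tuple[pd.DataFrame, list[dict], list[str]]:
    """Marker-level cohort -> labelled feature matrix.

    Subjects whose processing fails are excluded with the stage error
    recorded; the matrix is assembled from the remainder. Returns
    (matrix with label columns, exclusions, log lines)."""
    cohort: dict[str, dict] = {}
    labels: dict[str, dict] = {}
    exclusions: list[dict] = []
    log: list[str] = []
    for rec in recordings:
        try:
            res = process_recording(rec, config)
        except GaitError as exc:
            exclusions.append({"subject_id": rec.subject_id, "error": str(exc)})
            log.append(f"EXCLUDED {rec.subject_id}: {exc}")
            continue
        cohort[rec.subject_id] = res["discrete"]
        labels[rec.subject_id] = {
            "sex": rec.sex, "status": rec.status, "side": res["side"],
        }
        log.append(
            f"{rec.subject_id}: side={res['side']} "
            f"strides={config.strides}"
        )
    log.append(
        f"subjects in={len(recordings)} analysed={len(cohort)} "
        f"excluded={len(exclusions)}"
    )
    if not cohort:
        raise GaitError("no subject could be processed")
    return assemble_matrix(cohort, labels), exclusions, log


def features_from_cycles(
    cycles: dict[str, dict[tuple[str, str], np.ndarray]],
    subjects: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Waveform-level cohort (already one side per subject) -> labelled
    feature matrix, averaging the first ``config.strides`` strides."""
    cohort: dict[str, dict] = {}
    labels: dict[str, dict] = {}
    for sid, per_wave in cycles.items():
        disc = {}
        for waveform, arr in per_wave.items():
            arr = np.atleast_2d(arr)[: config.strides]
            disc[waveform] = average_strides(
                [extract_discrete(c) for c in arr], min(config.strides, arr.shape[0])
            )
        cohort[sid] = disc
        meta = subjects.loc[sid]
        labels[sid] = {
            "sex": meta["sex"], "status": meta["status"],
            "side": meta.get("affected_side") or "n/a",
        }
    return assemble_matrix(cohort, labels)


_COMPARISONS = {
    "sex": [("OA", "status", "sex"), ("control", "status", "sex")],
    "status": [("male", "sex", "status"), ("female", "sex", "status")],
}


def analyze_groups(
    X: pd.DataFrame, compare: str = "sex"
) -> dict[str, pd.DataFrame]:
    """The univariate pathway for the study's group comparisons.

    ``compare='sex'`` contrasts males vs females within the OA group and
    within controls; ``compare='status'`` contrasts OA vs control within
    each sex. ``X`` must carry ``sex`` and ``status`` label columns."""
    if compare not in _COMPARISONS:
        raise GaitError("compare must be 'sex' or 'status'")
    label_cols = [c for c in ("sex", "status", "side") if c in X.columns]
    out = {}
    for subset_value, subset_col, contrast_col in _COMPARISONS[compare]:
        sub = X[X[subset_col] == subset_value]
        if sub.empty:
            continue
        table = effect_size_table(
            sub.drop(columns=label_cols), sub[contrast_col].to_numpy()
        )
        out[f"{contrast_col}_within_{subset_value}"] = table
    return out


def classify_groups(
    X: pd.DataFrame,
    compare: str = "sex",
    pathway: str = "raw",
    config: PipelineConfig | None = None,
) -> dict[str, SelectionResult]:
    """The multivariate pathway (effect-size-ranked incremental linear SVM)
    for the same comparisons, on original variables (``pathway='raw'``) or
    PC scores (``pathway='pca'``)."""
    config = config or PipelineConfig()
    if compare not in _COMPARISONS:
        raise GaitError("compare must be 'sex' or 'status'")
    label_cols = [c for c in ("sex", "status", "side") if c in X.columns]
    out = {}
    for subset_value, subset_col, contrast_col in _COMPARISONS[compare]:
        sub = X[X[subset_col] == subset_value]
        if sub.empty:
            continue
        feats = sub.drop(columns=label_cols)
        y = sub[contrast_col].to_numpy()
        if pathway == "pca":
            res = run_pc_pathway(
                feats, y, mode=config.selection_mode,
                folds=config.cv_folds, seed=config.seed,
            )
        else:
            res = incremental_selection(
                feats.to_numpy(dtype=float), y, mode=config.selection_mode,
                folds=config.cv_folds, seed=config.seed,
                feature_names=list(feats.columns),
            )
        out[f"{contrast_col}_within_{subset_value}"] = res
    return out


def run_pipeline(
    config: PipelineConfig,
    input_dir: str | Path,
    out_dir: str | Path,
    compare: str = "sex",
) -> dict:
    """Full run over a cohort directory written by ``gaitdiff simulate``.

    The directory must contain ``subjects.csv`` plus either ``cycles.csv``
    (waveform level) or per-subject ``<id>_static.tsv``/``<id>_walk.tsv``
    marker trials. Writes the feature matrix, effect tables, selection
    results and a log; returns a summary dict."""
    config.validate()
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = pd.read_csv(input_dir / "subjects.csv", index_col="subject_id")

    log: list[str] = []
    exclusions: list[dict] = []
    if (input_dir / "cycles.csv").exists():
        cycles = gio.read_cycles_csv(input_dir / "cycles.csv")
        X = features_from_cycles(cycles, subjects, config)
        log.append(f"waveform-level input: {len(cycles)} subjects")
    else:
        recordings = []
        for sid, meta in subjects.iterrows():
            static, _ = gio.read_marker_tsv(input_dir / f"{sid}_static.tsv", config.marker_map)
            walk, rate = gio.read_marker_tsv(input_dir / f"{sid}_walk.tsv", config.marker_map)
            from .schema import MarkerTrajectory  # deferred: keep module import light

            recordings.append(
                SubjectRecording(
                    subject_id=str(sid),
                    sex=meta["sex"],
                    status=meta["status"],
                    affected_side=(None if pd.isna(meta.get("affected_side")) else meta["affected_side"]),
                    walking_speed=float(meta.get("speed", float("nan"))),
                    static_markers={k: v[0] if v.ndim == 2 else v for k, v in static.items()},
                    walking_markers={
                        k: MarkerTrajectory(k, "", v, rate) for k, v in walk.items()
                    },
                    sampling_rate=rate,
                )
            )
        X, exclusions, rec_log = features_from_recordings(recordings, config)
        log.extend(rec_log)

    X.to_csv(out_dir / "features.csv")
    tables = analyze_groups(X, compare=compare)
    for name, table in tables.items():
        table.to_csv(out_dir / f"effects_{name}.csv")
    results = {}
    for pathway in ("raw", "pca"):
        for name, res in classify_groups(X, compare, pathway, config).items():
            key = f"{pathway}_{name}"
            results[key] = res
            gio.write_selection_json(out_dir / f"selection_{key}.json", res)
    summary = {
        "subjects_in": int(len(subjects)),
        "subjects_analyzed": int(X.shape[0]),
        "subjects_excluded": len(exclusions),
        "exclusions": exclusions,
        "comparisons": {
            name: {
                "n_significant": int(t["significant"].sum()),
                "significant": list(t.index[t["significant"]]),
            }
            for name, t in tables.items()
        },
        "classification": {
            key: {
                "optimal_k": res.optimal_k,
                "max_accuracy": res.max_accuracy,
                "variance_explained": res.variance_explained,
            }
            for key, res in results.items()
        },
        "config": asdict(config),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "log.txt").write_text("\n".join(log) + "\n")
    return summary
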