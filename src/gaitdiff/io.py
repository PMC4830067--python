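"""Plain-text readers and writers.

Marker trials travel in a frozen TSV dialect — header ``frame\tmarker_id\t
x\ty\tz`` with coordinates in mm and an optional leading comment line
``# sampling_rate_hz: <float>`` — chosen over binary capture formats so
fixtures diff cleanly. Cycles, features and effect tables are CSV; selection
results and ground truth are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .schema import CYCLE_POINTS
from .selection import SelectionResult

_POINT_COLS = [f"point_{i}" for i in range(1, CYCLE_POINTS + 1)]


# ---------------------------------------------------------------------------
# marker TSV dialect
# ---------------------------------------------------------------------------

def write_marker_tsv(
    path: str | Path,
    markers: dict[str, np.ndarray],
    sampling_rate: float = 120.0,
) -> None:
    """Write marker positions (marker -> (n_frames, 3) or (3,) array, mm)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz: {sampling_rate}\n")
        fh.write("frame\tmarker_id\tx\ty\tz\n")
        for name in sorted(markers):
            pos = np.atleast_2d(np.asarray(markers[name], dtype=float))
            for i, (x, y, z) in enumerate(pos):
                fh.write(f"{i}\t{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_marker_tsv(
    path: str | Path,
    marker_map: dict[str, str] | None = None,
) -> tuple[dict[str, np.ndarray], float]:
    """Read the TSV marker dialect.

    Returns (marker -> (n_frames, 3) array, sampling rate in Hz; 120 if the
    file carries no rate comment). Marker names are passed through
    ``marker_map`` when given; unmapped names raise :class:`FormatError`.
    """
    path = Path(path)
    sampling_rate = 120.0
    with path.open() as fh:
        first = fh.readline()
        data_start = 2
        if first.startswith("#"):
            try:
                sampling_rate = float(first.split(":", 1)[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"bad rate comment in {path}: {first!r}") from exc
            header = fh.readline()
            data_start = 3
        else:
            header = first
        cols = header.rstrip("\n").split("\t")
        if cols != ["frame", "marker_id", "x", "y", "z"]:
            raise FormatError(f"unexpected TSV header in {path}: {cols}")
        frames: dict[str, list[tuple[int, list[float]]]] = {}
        for lineno, line in enumerate(fh, start=data_start):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 or any(p == "" for p in parts):
                raise FormatError(f"{path}: malformed row at line {lineno}")
            try:
                idx = int(parts[0])
                xyz = [float(v) for v in parts[2:5]]
            except ValueError as exc:
                raise FormatError(f"{path}: bad value at line {lineno}") from exc
            name = parts[1]
            if marker_map is not None:
                if name not in marker_map:
                    raise FormatError(f"{path}: unmapped marker name {name!r}")
                name = marker_map[name]
            frames.setdefault(name, []).append((idx, xyz))
    out: dict[str, np.ndarray] = {}
    n = None
    for name, rows in frames.items():
        rows.sort(key=lambda r: r[0])
        arr = np.array([xyz for _, xyz in rows], dtype=float)
        if n is None:
            n = arr.shape[0]
        elif arr.shape[0] != n:
            raise FormatError(f"{path}: marker {name} has {arr.shape[0]} frames, expected {n}")
        out[name] = arr
    return out, sampling_rate


# ---------------------------------------------------------------------------
# cycles / features / events CSV
# ---------------------------------------------------------------------------

def write_cycles_csv(
    path: str | Path,
    cycles: dict[str, dict[tuple[str, str], np.ndarray]],
) -> None:
    """subject_id, joint, plane, stride, point_1..point_100."""
    rows = []
    for sid, per_wave in cycles.items():
        for (joint, plane), arr in per_wave.items():
            for k, stride in enumerate(np.atleast_2d(arr)):
                rows.append([sid, joint, plane, k, *stride])
    df = pd.DataFrame(rows, columns=["subject_id", "joint", "plane", "stride", *_POINT_COLS])
    df.to_csv(path, index=False)


def read_cycles_csv(path: str | Path) -> dict[str, dict[tuple[str, str], np.ndarray]]:
    df = pd.read_csv(path)
    missing = {"subject_id", "joint", "plane", "stride", *_POINT_COLS} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)[:4]}...")
    out: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for (sid, joint, plane), block in df.groupby(
        ["subject_id", "joint", "plane"], sort=False
    ):
        block = block.sort_values("stride")
        out.setdefault(str(sid), {})[(joint, plane)] = block[_POINT_COLS].to_numpy(
            dtype=float
        )
    return out


def write_events_csv(path: str | Path, events: dict[str, dict[str, np.ndarray]]) -> None:
    """subject_id, side, stride, heel_strike_frame, toe_off_frame."""
    rows = []
    for sid, per_side in events.items():
        for side, ev in per_side.items():
            hs, to = np.asarray(ev["heel_strikes"]), np.asarray(ev["toe_offs"])
            for k in range(to.size):
                rows.append([sid, side, k, int(hs[k]), int(to[k])])
    pd.DataFrame(
        rows,
        columns=["subject_id", "side", "stride", "heel_strike_frame", "toe_off_frame"],
    ).to_csv(path, index=False)


def write_selection_json(path: str | Path, result: SelectionResult) -> None:
    payload = asdict(result)
    payload["ranking"] = [int(i) for i in result.ranking]
    payload["accuracy_curve"] = [float(a) for a in result.accuracy_curve]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_selection_json(path: str | Path) -> SelectionResult:
    payload = json.loads(Path(path).read_text())
    payload["ranking"] = np.asarray(payload["ranking"], dtype=int)
    payload["accuracy_curve"] = np.asarray(payload["accuracy_curve"], dtype=float)
    return SelectionResult(**payload)


def effect_table_to_json(effect_table: dict) -> dict:
    """Serializable form of a synthetic effect table."""
    return {
        "|".join(key): {g: list(map(float, ms)) for g, ms in entry.items()}
        for key, entry in effect_table.items()
    }


def effect_table_from_json(payload: dict) -> dict:
    return {
        tuple(key.split("|")): {g: tuple(v) for g, v in entry.items()}
        for key, entry in payload.items()
    }
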