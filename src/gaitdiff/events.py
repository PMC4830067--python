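"""Gait event detection and time normalization of joint-angle waveforms.

On a treadmill, initial contact (heel strike) occurs at the most anterior
position the superior calcaneal marker reaches in each cycle, and toe-off at
the most posterior position of the anterior shoe (toe) marker. Both are
per-cycle local extrema of the marker's anterior-posterior coordinate; a
refractory period of half the median cycle length suppresses noise peaks.

Each stride is then resampled onto a fixed 100-point grid: the stance phase
(heel strike to toe-off) onto 60 points and the swing phase (toe-off to the
next heel strike) onto 40 points, by linear interpolation. Point 1 is the
touchdown sample, point 60 the toe-off sample.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientStridesError, InvalidCycleError, NoEventsError
from .schema import (
    GaitCycle,
    GaitEvents,
    STANCE_POINTS,
    SWING_POINTS,
)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of per-cycle local maxima.

    Secondary wiggles (e.g. segment-rotation wobble of a marker near the
    opposite extreme of the cycle) are rejected by a prominence criterion of
    a quarter of the signal range; a refractory period of half the median
    inter-peak interval then suppresses residual noise peaks."""
    x = np.asarray(x, dtype=float)
    prom = 0.25 * float(np.ptp(x))
    kwargs = {"prominence": prom} if prom > 0 else {}
    peaks, _ = find_peaks(x, plateau_size=(1, None), **kwargs)
    if peaks.size == 0:
        raise NoEventsError("no local maxima found in the marker trajectory")
    if peaks.size > 1:
        period = np.median(np.diff(peaks))
        min_distance = max(1, int(round(0.5 * period)))
        peaks, _ = find_peaks(x, distance=min_distance, **kwargs)
    return peaks


def detect_heel_strikes(calcaneal_ap: np.ndarray) -> np.ndarray:
    """Heel-strike frames: per-cycle maxima of the superior calcaneal
    marker's anterior coordinate. Raises :class:`NoEventsError` for
    monotone input."""
    return _local_maxima(calcaneal_ap)


def detect_toe_offs(toe_ap: np.ndarray) -> np.ndarray:
    """Toe-off frames: per-cycle minima (posterior extremes) of the toe
    marker's anterior coordinate."""
    return _local_maxima(-np.asarray(toe_ap, dtype=float))


def pair_events(heel_strikes: np.ndarray, toe_offs: np.ndarray) -> GaitEvents:
    """Keep toe-offs that fall strictly between consecutive heel strikes
    (one per stride) and the heel strikes that bracket them."""
    hs = np.sort(np.asarray(heel_strikes, dtype=int))
    to = np.sort(np.asarray(toe_offs, dtype=int))
    kept_hs: list[int] = []
    kept_to: list[int] = []
    for a, b in zip(hs[:-1], hs[1:]):
        inside = to[(to > a) & (to < b)]
        if inside.size:
            kept_hs.append(int(a))
            # if several candidates survive, take the first (stance terminus)
            kept_to.append(int(inside[0]))
    if not kept_hs:
        raise NoEventsError("no heel-strike/toe-off alternation found")
    kept_hs.append(int(hs[np.searchsorted(hs, kept_to[-1])]))
    events = GaitEvents(np.array(kept_hs), np.array(kept_to))
    validate_events(events)
    return events


def validate_events(events: GaitEvents) -> None:
    hs, to = events.heel_strikes, events.toe_offs
    if hs.size < 2 or to.size != hs.size - 1:
        raise NoEventsError("need >=2 heel strikes with one toe-off per stride")
    if np.any(np.diff(hs) <= 0) or np.any(np.diff(to) <= 0):
        raise NoEventsError("event frames must be strictly increasing")
    if np.any(to <= hs[:-1]) or np.any(to >= hs[1:]):
        raise NoEventsError("each toe-off must fall strictly between heel strikes")


def _resample_linear(segment: np.ndarray, n_out: int) -> np.ndarray:
    """Linearly resample a segment (inclusive endpoints) onto n_out points."""
    m = segment.shape[0]
    if m < 2:
        raise InvalidCycleError("phase segment needs >=2 frames")
    xi = np.linspace(0.0, m - 1.0, n_out)
    return np.interp(xi, np.arange(m), segment)


def segment_normalize(
    angles: np.ndarray,
    events: GaitEvents,
    strides: int = 10,
    settle_strides: int = 2,
) -> list[GaitCycle]:
    """Cut an angle series into time-normalized 100-point gait cycles.

    For each stride, frames from heel strike to toe-off (inclusive) are
    resampled to 60 stance points and frames from toe-off to the next heel
    strike to 40 swing points; the toe-off sample itself is stance point 60,
    and swing point 61 is the first post-toe-off grid sample. The first
    ``settle_strides`` complete cycles are skipped (treadmill settling) and
    the next ``strides`` consecutive cycles returned.
    """
    validate_events(events)
    a = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidCycleError("angle series contains non-finite values")
    hs, to = events.heel_strikes, events.toe_offs
    n_available = hs.size - 1
    if n_available - settle_strides < strides:
        raise InsufficientStridesError(
            f"requested {strides} strides after skipping {settle_strides}, "
            f"but only {n_available} complete cycles are available"
        )
    cycles: list[GaitCycle] = []
    for k in range(settle_strides, settle_strides + strides):
        stance = _resample_linear(a[hs[k] : to[k] + 1], STANCE_POINTS)
        # swing grid starts one normalized step after toe-off so that point
        # 60 (toe-off) is not duplicated
        swing_seg = a[to[k] : hs[k + 1] + 1]
        m = swing_seg.shape[0]
        xi = np.linspace(0.0, m - 1.0, SWING_POINTS + 1)[1:]
        swing = np.interp(xi, np.arange(m), swing_seg)
        cycles.append(GaitCycle(np.concatenate([stance, swing]), stride=k))
    return cycles
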