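"""Trial cleaning, filtering, trimming and phase segmentation.

A trial is segmented into three phases:

* standing — a 30 s window starting at movie onset, additionally clipped to
  end no later than 5 s before the participant unloads the force plate;
* gait initiation — the first two steps taken off the plate;
* walking — all full gait cycles after the turn at station A.

Filtering is zero-phase (forward-backward) second-order Butterworth, 10 Hz
for motion and 20 Hz for force channels by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from . import gait_features
from .gait_features import GaitEvents, Step
from .mocap_io import ForcePlateRecord, MarkerTrajectorySet, TrialRecording


class SegmentationError(ValueError):
    """A required phase could not be identified."""


@dataclass
class PhaseSegmentation:
    """Phase boundaries and gait events of one trial (times in seconds)."""

    standing_window: tuple[float, float]
    offload_time: float
    turn_time: float | None
    events: dict[str, GaitEvents]
    initiation_steps: list[Step]
    walking_cycles: dict[str, list[tuple[float, float, float]]]  # (hs, to, hs)


# ---------------------------------------------------------------------------
# Gap filling and filtering
# ---------------------------------------------------------------------------

def _fill_column(col: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    missing = np.isnan(col)
    if not missing.any():
        return col
    if missing[0] or missing[-1]:
        raise ValueError(f"marker {name!r}: gap at sequence boundary")
    idx = np.flatnonzero(missing)
    # split into contiguous runs and check lengths
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        if run.size > max_gap:
            raise ValueError(
                f"marker {name!r}: gap of {run.size} frames exceeds max_gap={max_gap}"
            )
    valid = ~missing
    spline = CubicSpline(np.flatnonzero(valid), col[valid])
    out = col.copy()
    out[missing] = spline(idx)
    return out


def fill_gaps(m: MarkerTrajectorySet, max_gap: int = 100) -> MarkerTrajectorySet:
    """Fill missing marker runs by cubic interpolation against time.

    Gaps longer than ``max_gap`` frames, or touching a sequence boundary,
    raise ``ValueError`` (they cannot be interpolated reliably).
    """
    data = {}
    for name, arr in m.data.items():
        if np.isnan(arr).any():
            arr = np.column_stack(
                [_fill_column(arr[:, j].copy(), max_gap, name) for j in range(3)]
            )
        data[name] = arr.copy()
    return MarkerTrajectorySet(m.rate, data)


def butterworth_lowpass(
    x: np.ndarray,
    cutoff: float,
    rate: float,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter along axis 0.

    With ``zero_phase`` the filter is applied forward and backward
    (no phase lag; the effective magnitude response is squared, so the gain
    at the cutoff is 0.5 rather than 1/sqrt(2)).
    """
    if cutoff >= rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz at or above Nyquist ({rate / 2} Hz)")
    b, a = butter(order, cutoff, btype="low", fs=rate)
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return filtfilt(b, a, x, axis=0)
    from scipy.signal import lfilter

    return lfilter(b, a, x, axis=0)


def filter_trial(
    t: TrialRecording,
    marker_cutoff: float = 10.0,
    force_cutoff: float = 20.0,
) -> TrialRecording:
    """Low-pass the marker (10 Hz) and force (20 Hz) channels of a trial."""
    markers = MarkerTrajectorySet(
        t.markers.rate,
        {
            k: butterworth_lowpass(v, marker_cutoff, t.markers.rate)
            for k, v in t.markers.data.items()
        },
    )
    fp = t.forceplate
    kwargs = {}
    for name in ("forces", "moments", "cop"):
        arr = getattr(fp, name)
        kwargs[name] = (
            butterworth_lowpass(arr, force_cutoff, fp.rate) if arr is not None else None
        )
    forceplate = ForcePlateRecord(rate=fp.rate, z0=fp.z0, **kwargs)
    return replace(t, markers=markers, forceplate=forceplate)


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_trial(
    t: TrialRecording,
    station_b: tuple[float, float],
    radius: float = 0.5,
    offset: float = 0.5,
    body_marker: str = "SACRUM",
) -> TrialRecording:
    """Truncate a trial ``offset`` seconds before the body marker first comes
    within ``radius`` metres (horizontal) of station B."""
    if body_marker not in t.markers.data:
        raise ValueError(f"body marker {body_marker!r} absent")
    pos = t.markers.data[body_marker][:, :2]
    dist = np.hypot(pos[:, 0] - station_b[0], pos[:, 1] - station_b[1])
    inside = np.flatnonzero(dist <= radius)
    if inside.size == 0:
        raise ValueError("participant never reaches station B")
    t_arrival = inside[0] / t.markers.rate
    t_end = t_arrival - offset
    if t_end <= 0:
        raise ValueError("trim removes the whole trial")
    markers = t.markers.window(0.0, t_end)
    fp = t.forceplate
    n_fp = int(np.floor(t_end * fp.rate))
    kwargs = {
        name: (getattr(fp, name)[:n_fp].copy() if getattr(fp, name) is not None else None)
        for name in ("forces", "moments", "cop")
    }
    forceplate = ForcePlateRecord(rate=fp.rate, z0=fp.z0, **kwargs)
    return replace(t, markers=markers, forceplate=forceplate)


# ---------------------------------------------------------------------------
# Phase segmentation
# ---------------------------------------------------------------------------

def _sustained_below(x: np.ndarray, threshold: float, n_sustain: int) -> int | None:
    """Index of the first run of >= n_sustain consecutive samples below
    ``threshold``, or None."""
    below = x < threshold
    if n_sustain <= 1:
        idx = np.flatnonzero(below)
        return int(idx[0]) if idx.size else None
    kernel = np.ones(n_sustain, dtype=int)
    runs = np.convolve(below.astype(int), kernel, mode="valid") == n_sustain
    idx = np.flatnonzero(runs)
    return int(idx[0]) if idx.size else None


def detect_plate_offload(
    fp: ForcePlateRecord,
    frac_of_body_weight: float = 0.5,
    sustain_s: float = 0.2,
    weight_window_s: float = 5.0,
) -> float:
    """Time at which vertical force drops below ``frac_of_body_weight`` of the
    body weight, sustained for ``sustain_s`` seconds."""
    if fp.forces is None:
        raise ValueError("force channels required for off-load detection")
    fz = fp.forces[:, 2]
    n_bw = max(1, int(weight_window_s * fp.rate))
    body_weight = float(np.median(fz[:n_bw]))
    if body_weight <= 0:
        raise ValueError("non-positive body weight estimate")
    i = _sustained_below(fz, frac_of_body_weight * body_weight, max(1, int(sustain_s * fp.rate)))
    if i is None:
        raise SegmentationError("no plate off-load found")
    return i / fp.rate


def detect_turn(
    m: MarkerTrajectorySet,
    after: float,
    sustain_s: float = 0.3,
    speed_threshold: float = 0.05,
    body_marker: str = "SACRUM",
) -> float | None:
    """Start of the first sustained reversal of the pelvis anterior velocity
    after time ``after`` (the end of the turn at station A)."""
    pos = m.data[body_marker][:, 0]
    vx = np.gradient(pos) * m.rate
    vx = butterworth_lowpass(vx, 2.0, m.rate)
    i0 = int(after * m.rate)
    i = _sustained_below(vx[i0:], -speed_threshold, max(1, int(sustain_s * m.rate)))
    return None if i is None else (i0 + i) / m.rate


def segment_phases(
    t: TrialRecording,
    movie_onset: float = 0.0,
    standing_window_s: float = 30.0,
    offload_guard_s: float = 5.0,
    min_standing_s: float = 5.0,
    offload_frac: float = 0.5,
    offload_sustain_s: float = 0.2,
    event_kwargs: dict | None = None,
) -> PhaseSegmentation:
    """Segment a trial into standing, gait initiation and walking.

    The standing window is the first ``standing_window_s`` seconds after movie
    onset intersected with "ends ``offload_guard_s`` s before plate off-load"
    (both constraints applied, conservatively).
    """
    offload = detect_plate_offload(
        t.forceplate, frac_of_body_weight=offload_frac, sustain_s=offload_sustain_s
    )
    end = min(movie_onset + standing_window_s, offload - offload_guard_s)
    if end - movie_onset < min_standing_s:
        raise SegmentationError(
            f"standing window of {end - movie_onset:.2f} s shorter than required"
        )
    standing = (movie_onset, end)

    events = {
        side: gait_features.detect_gait_events(t.markers, side, **(event_kwargs or {}))
        for side in ("left", "right")
    }

    steps = _steps_from_events(events)
    first = _first_step(t, events, offload)
    if first is not None and not any(
        s.side == first.side and abs(s.heel_strike - first.heel_strike) < 0.05
        for s in steps
    ):
        steps = sorted(steps + [first], key=lambda s: s.toe_off)
    initiation = [s for s in steps if s.heel_strike > offload - 1.0][:2]
    if len(initiation) < 2:
        raise SegmentationError("fewer than two gait-initiation steps detected")

    turn = detect_turn(t.markers, after=initiation[-1].heel_strike)
    cycles: dict[str, list[tuple[float, float, float]]] = {"left": [], "right": []}
    if turn is not None:
        for side in ("left", "right"):
            ev = events[side]
            hs = [x for x in ev.heel_strike_times if x >= turn]
            for a, b in zip(hs, hs[1:]):
                tos = [x for x in ev.toe_off_times if a < x < b]
                if tos:
                    cycles[side].append((a, tos[0], b))
    if not (cycles["left"] or cycles["right"]):
        raise SegmentationError("no gait cycles")
    return PhaseSegmentation(
        standing_window=standing,
        offload_time=offload,
        turn_time=turn,
        events=events,
        initiation_steps=initiation,
        walking_cycles=cycles,
    )


def _first_step(
    t: TrialRecording, events: dict[str, GaitEvents], offload: float,
    speed_threshold: float = 0.2, lookback_s: float = 0.9,
) -> Step | None:
    """The first step off the plate, recovering its toe-off kinematically.

    The first toe-off of a bout that starts from rest sits at the end of a
    long plateau of the projected hip-toe distance, so it has no prominence
    as a local minimum; this mirrors the practice of identifying the first
    steps with the force-plate record: the step is anchored at the first heel
    strike near plate off-load and its toe-off is the onset of toe movement.
    """
    m = t.markers
    candidates = sorted(
        (hs, side)
        for side, ev in events.items()
        for hs in ev.heel_strike_times
        if hs > offload - 1.0
    )
    for hs, side in candidates[:4]:
        toe = m.data[gait_features.SIDE_PREFIX[side] + "TOE"]
        speed = np.linalg.norm(np.gradient(toe, axis=0), axis=1) * m.rate
        speed = butterworth_lowpass(speed, 5.0, m.rate)
        i_hs = int(hs * m.rate)
        i_lo = max(0, i_hs - int(lookback_s * m.rate))
        moving = speed[i_lo:i_hs] > speed_threshold
        if moving.any():
            onset = i_lo + int(np.argmax(moving))
            return Step(side=side, toe_off=onset / m.rate, heel_strike=hs)
    return None


def _steps_from_events(events: dict[str, GaitEvents]) -> list[Step]:
    """Chronological (toe-off, next ipsilateral heel-strike) swings."""
    steps = []
    for side, ev in events.items():
        hs = np.asarray(ev.heel_strike_times)
        for to in ev.toe_off_times:
            later = hs[hs > to]
            if later.size:
                steps.append(Step(side=side, toe_off=float(to), heel_strike=float(later[0])))
    steps.sort(key=lambda s: s.toe_off)
    # drop duplicated heel strikes (two toe-offs mapping to one strike)
    seen, out = set(), []
    for s in steps:
        key = (s.side, s.heel_strike)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out
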