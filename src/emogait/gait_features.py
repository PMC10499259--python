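"""Gait event detection and gait-initiation / walking parameters.

Events follow the coordinate-based convention for overground walking: with the
hip (greater trochanter), heel and toe displacements projected on the
instantaneous direction of progression, a heel strike is a local maximum of
the hip-to-heel projected distance and a toe-off a local minimum of the
hip-to-toe projected distance.  Candidate extrema are gated by a minimum peak
separation, a prominence floor and a minimum pelvis speed (which suppresses
spurious extrema while standing or turning).

Lengths are normalized by leg length L, times by sqrt(L/g) and speeds by
sqrt(g*L), removing body-size effects (dimensionless, Froude-consistent
scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .mocap_io import MarkerTrajectorySet

G = 9.81  # m/s^2

SIDE_PREFIX = {"left": "L_", "right": "R_"}


@dataclass
class GaitEvents:
    """Heel-strike and toe-off events of one side, as frames and seconds."""

    side: str
    rate: float
    heel_strike_frames: np.ndarray
    toe_off_frames: np.ndarray

    @property
    def heel_strike_times(self) -> np.ndarray:
        return self.heel_strike_frames / self.rate

    @property
    def toe_off_times(self) -> np.ndarray:
        return self.toe_off_frames / self.rate


@dataclass
class Step:
    side: str
    toe_off: float
    heel_strike: float


@dataclass
class StepMetrics:
    """One step: raw metrics plus leg-length-normalized variants."""

    side: str
    length: float
    duration: float
    height: float
    width: float
    speed: float = field(init=False)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("step duration must be positive")
        self.speed = self.length / self.duration

    def normalized(self, L: float) -> dict[str, float]:
        return {
            "length": normalize(self.length, "length", L),
            "duration": normalize(self.duration, "time", L),
            "speed": normalize(self.speed, "speed", L),
            "height": normalize(self.height, "length", L),
            "width": normalize(self.width, "length", L),
        }


# ---------------------------------------------------------------------------
# Heading and event detection
# ---------------------------------------------------------------------------

def _heading_and_speed(
    m: MarkerTrajectorySet, body_marker: str = "SACRUM"
) -> tuple[np.ndarray, np.ndarray]:
    """Unit horizontal direction of progression and speed of the pelvis.

    The velocity is low-passed at 1 Hz so the heading flips cleanly at the
    turn; frames where the pelvis is (near) stationary keep the last valid
    heading.
    """
    pos = m.data[body_marker][:, :2]
    vel = np.gradient(pos, axis=0) * m.rate
    if m.n_frames > 30:
        b, a = butter(2, 1.0, btype="low", fs=m.rate)
        vel = filtfilt(b, a, vel, axis=0)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    heading = np.zeros_like(vel)
    heading[:, 0] = 1.0
    moving = speed > 0.05
    heading[moving] = vel[moving] / speed[moving, None]
    # propagate last moving heading into stationary stretches
    if moving.any():
        idx = np.where(moving, np.arange(len(speed)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(moving)
        idx[idx < 0] = first
        heading = heading[idx] if False else np.where(
            moving[:, None], heading, heading[idx]
        )
    return heading, speed


def pick_extrema(
    x: np.ndarray,
    rate: float,
    min_separation_s: float = 0.4,
    prominence: float = 0.02,
) -> np.ndarray:
    """Indices of local maxima of ``x`` gated by separation and prominence."""
    peaks, _ = find_peaks(
        x, distance=max(1, round(min_separation_s * rate)), prominence=prominence
    )
    return peaks


def detect_gait_events(
    m: MarkerTrajectorySet,
    side: str,
    min_separation_s: float = 0.4,
    prominence: float = 0.02,
    min_speed: float = 0.25,
    body_marker: str = "SACRUM",
) -> GaitEvents:
    """Detect heel strikes and toe-offs of one side from marker kinematics."""
    p = SIDE_PREFIX[side]
    for name in (p + "TROCH", p + "HEEL", p + "TOE", body_marker):
        if name not in m.data:
            raise ValueError(f"required marker {name!r} absent")
    heading, speed = _heading_and_speed(m, body_marker)
    # gate on the rolling max pelvis speed (+-0.25 s) so events at the very
    # start of a walking bout, where the pelvis is still accelerating, survive
    from scipy.ndimage import maximum_filter1d

    speed_win = maximum_filter1d(speed, size=max(1, int(0.5 * m.rate) | 1))
    hip = m.data[p + "TROCH"][:, :2]
    heel_proj = ((m.data[p + "HEEL"][:, :2] - hip) * heading).sum(axis=1)
    toe_proj = ((m.data[p + "TOE"][:, :2] - hip) * heading).sum(axis=1)
    hs = pick_extrema(heel_proj, m.rate, min_separation_s, prominence)
    to = pick_extrema(-toe_proj, m.rate, min_separation_s, prominence)
    hs = hs[speed_win[hs] >= min_speed]
    to = to[speed_win[to] >= min_speed]
    return GaitEvents(
        side=side, rate=m.rate, heel_strike_frames=hs, toe_off_frames=to
    )


# ---------------------------------------------------------------------------
# Leg length and dimensionless normalization
# ---------------------------------------------------------------------------

def leg_length_estimate(
    m: MarkerTrajectorySet, standing_window: tuple[float, float]
) -> float:
    """Leg length as the mean vertical height of the greater-trochanter
    markers above the floor plane (z = 0) during quiet standing."""
    w = m.window(*standing_window)
    heights = []
    for name in ("L_TROCH", "R_TROCH"):
        if name in w.data:
            heights.append(np.nanmean(w.data[name][:, 2]))
    if not heights:
        raise ValueError("trochanter markers absent")
    return float(np.mean(heights))


def normalize(value: float, kind: str, L: float, g: float = G) -> float:
    """Dimensionless gait normalization by leg length.

    length -> value / L ; time -> value / sqrt(L/g) ; speed -> value / sqrt(g*L).
    """
    if L <= 0:
        raise ValueError("leg length must be positive")
    if kind == "length":
        return value / L
    if kind == "time":
        return value / np.sqrt(L / g)
    if kind == "speed":
        return value / np.sqrt(g * L)
    raise ValueError(f"unknown normalization kind {kind!r}")


# ---------------------------------------------------------------------------
# Step geometry helpers
# ---------------------------------------------------------------------------

def _frame(t: float, rate: float, n: int) -> int:
    return int(np.clip(round(t * rate), 0, n - 1))


def _heading_at(m: MarkerTrajectorySet, t: float) -> tuple[np.ndarray, np.ndarray]:
    heading, _ = _heading_and_speed(m)
    f = _frame(t, m.rate, m.n_frames)
    u = heading[f]
    nvec = np.array([-u[1], u[0]])
    return u, nvec


def _path_length(xyz: np.ndarray) -> float:
    return float(np.sqrt((np.diff(xyz, axis=0) ** 2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# Gait initiation
# ---------------------------------------------------------------------------

def gait_initiation_features(
    m: MarkerTrajectorySet,
    initiation_steps: list[Step],
    events: dict[str, GaitEvents],
    L: float,
    standing_window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Metrics of the first two steps off the force plate.

    A step spans its toe-off to the next toe-off of either foot (swing plus
    the subsequent loading/double-support phase); lengths are heel
    displacements projected on the direction of progression.
    """
    if len(initiation_steps) < 2:
        raise ValueError("fewer than two gait-initiation steps")
    rate, n = m.rate, m.n_frames
    heading, _ = _heading_and_speed(m)
    out: dict[str, float] = {}
    all_to = np.sort(np.concatenate([events[s].toe_off_times for s in events]))

    def duration_of(step: Step) -> float:
        later = all_to[all_to > step.toe_off + 0.05]
        if later.size:
            return float(later[0] - step.toe_off)
        return step.heel_strike - step.toe_off
    stand_z = {}
    if standing_window is not None:
        for p in ("L_", "R_"):
            wz = m.window(*standing_window).data[p + "HEEL"][:, 2]
            stand_z[p] = float(np.nanmean(wz))
    for k, step in enumerate(initiation_steps[:2], start=1):
        p = SIDE_PREFIX[step.side]
        q = SIDE_PREFIX["left" if step.side == "right" else "right"]
        heel = m.data[p + "HEEL"]
        other = m.data[q + "HEEL"]
        f_to = _frame(step.toe_off, rate, n)
        f_hs = _frame(step.heel_strike, rate, n)
        u = heading[f_hs]
        nvec = np.array([-u[1], u[0]])
        disp = heel[f_hs, :2] - heel[f_to, :2]
        length = float(disp @ u)
        duration = duration_of(step)
        base_z = stand_z.get(p, float(heel[f_to, 2]))
        height = float(heel[f_to : f_hs + 1, 2].max() - base_z)
        width = float(abs((heel[f_hs, :2] - other[f_hs, :2]) @ nvec))
        metrics = StepMetrics(
            side=step.side, length=length, duration=duration, height=height, width=width
        )
        norm = metrics.normalized(L)
        key = f"step{k}"
        for pname, raw in (
            ("length", metrics.length),
            ("duration", metrics.duration),
            ("speed", metrics.speed),
            ("height", metrics.height),
            ("width", metrics.width),
        ):
            out[f"gait_initiation.{key}.raw.{pname}"] = raw
            out[f"gait_initiation.{key}.normalized.{pname}"] = (
                norm[pname] if pname != "speed" else normalize(metrics.speed, "speed", L)
            )
        if k == 1:
            swing_dur = step.heel_strike - step.toe_off
            path = _path_length(heel[f_to : f_hs + 1])
            swing_speed = path / swing_dur if swing_dur > 0 else np.nan
            lateral = (heel[f_to : f_hs + 1, :2] - heel[f_to, :2]) @ nvec
            swing_width = float(np.abs(lateral).max())
            out["gait_initiation.step1.raw.swing_speed"] = swing_speed
            out["gait_initiation.step1.normalized.swing_speed"] = normalize(
                swing_speed, "speed", L
            )
            out["gait_initiation.step1.raw.swing_width"] = swing_width
            out["gait_initiation.step1.normalized.swing_width"] = normalize(
                swing_width, "length", L
            )
    total = initiation_steps[1].heel_strike - initiation_steps[0].toe_off
    out["gait_initiation.overall.raw.total_duration"] = total
    out["gait_initiation.overall.normalized.total_duration"] = normalize(total, "time", L)
    return out


# ---------------------------------------------------------------------------
# Walking
# ---------------------------------------------------------------------------

WALKING_PARAMS = (
    "step_length",
    "step_duration",
    "step_speed",
    "step_height",
    "step_width",
    "stance_duration",
    "swing_duration",
    "swing_speed",
    "stride_length",
    "stride_duration",
    "double_support_duration",
    "ds_distance_by_stance",
)

_NORM_KIND = {
    "step_length": "length",
    "step_duration": "time",
    "step_speed": "speed",
    "step_height": "length",
    "step_width": "length",
    "stance_duration": "time",
    "swing_duration": "time",
    "swing_speed": "speed",
    "stride_length": "length",
    "stride_duration": "time",
    "double_support_duration": "time",
    "ds_distance_by_stance": "speed",
    "walking_speed": "speed",
    "total_duration": "time",
}


STEP_PARAMS = ("step_length", "step_duration", "step_speed", "step_width")


def _step_metrics(
    m: MarkerTrajectorySet, side: str, hs: float, contra_events: GaitEvents
) -> dict[str, float] | None:
    """Step-level parameters at one landing (needs only the preceding
    contralateral contact, not a full same-side cycle)."""
    rate, n = m.rate, m.n_frames
    p = SIDE_PREFIX[side]
    q = SIDE_PREFIX["left" if side == "right" else "right"]
    contra_hs = contra_events.heel_strike_times
    prior = contra_hs[(contra_hs < hs) & (contra_hs > hs - 1.5)]
    if prior.size == 0:
        return None
    hs_c = float(prior[-1])
    f1 = _frame(hs, rate, n)
    u, nvec = _heading_at(m, hs)
    delta = m.data[p + "HEEL"][f1, :2] - m.data[q + "HEEL"][f1, :2]
    res = {
        "step_length": float(delta @ u),
        "step_duration": hs - hs_c,
        "step_width": float(abs(delta @ nvec)),
    }
    res["step_speed"] = res["step_length"] / res["step_duration"]
    return res


def _cycle_metrics(
    m: MarkerTrajectorySet,
    side: str,
    cycle: tuple[float, float, float],
    contra_events: GaitEvents,
    body_marker: str = "SACRUM",
) -> dict[str, float]:
    hs0, to, hs1 = cycle
    rate, n = m.rate, m.n_frames
    p = SIDE_PREFIX[side]
    heel = m.data[p + "HEEL"]
    sacrum = m.data[body_marker]
    u, _ = _heading_at(m, hs1)
    f0, ft, f1 = (_frame(t, rate, n) for t in (hs0, to, hs1))
    contra_to = contra_events.toe_off_times
    ds_end = contra_to[(contra_to > hs0) & (contra_to < hs1)]
    res: dict[str, float] = {}
    res["stride_length"] = float((heel[f1, :2] - heel[f0, :2]) @ u)
    res["stride_duration"] = hs1 - hs0
    res["stance_duration"] = to - hs0
    res["swing_duration"] = hs1 - to
    swing_path = _path_length(heel[ft : f1 + 1])
    res["swing_speed"] = swing_path / res["swing_duration"]
    res["step_height"] = float(heel[ft : f1 + 1, 2].max() - heel[f0 : f1 + 1, 2].min())
    if ds_end.size:
        t_ds = float(ds_end[0])
        res["double_support_duration"] = t_ds - hs0
        f_ds = _frame(t_ds, rate, n)
        ds_dist = float((sacrum[f_ds, :2] - sacrum[f0, :2]) @ u)
        res["ds_distance_by_stance"] = ds_dist / res["stance_duration"]
    else:
        res["double_support_duration"] = np.nan
        res["ds_distance_by_stance"] = np.nan
    return res


def walking_features(
    m: MarkerTrajectorySet,
    walking_cycles: dict[str, list[tuple[float, float, float]]],
    events: dict[str, GaitEvents],
    L: float,
    t_start: float | None = None,
) -> dict[str, float]:
    """Per-side aggregates (mean and SD) of the walking parameters after the
    turn, raw and leg-length-normalized.

    Step-level parameters are sampled at every landing with a preceding
    contralateral contact; cycle-level parameters (stance, swing, stride,
    double support, step height) at every full same-side gait cycle.
    """
    out: dict[str, float] = {}
    all_speed: list[float] = []
    if t_start is None:
        starts = [c[0] for cycles in walking_cycles.values() for c in cycles]
        t_start = min(starts) - 0.5 if starts else 0.0
    for side in ("left", "right"):
        contra = events["left" if side == "right" else "right"]
        cycle_rows = [
            _cycle_metrics(m, side, c, contra) for c in walking_cycles.get(side, [])
        ]
        own_hs = events[side].heel_strike_times
        step_rows = [
            r
            for hs in own_hs[own_hs > t_start]
            if (r := _step_metrics(m, side, hs, contra)) is not None
        ]
        for param in WALKING_PARAMS:
            rows = step_rows if param in STEP_PARAMS else cycle_rows
            vals = np.array([r[param] for r in rows], dtype=float)
            vals = vals[~np.isnan(vals)]
            mean = float(vals.mean()) if vals.size else np.nan
            sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            kind = _NORM_KIND[param]
            out[f"walking.{side}.raw.mean.{param}"] = mean
            out[f"walking.{side}.raw.sd.{param}"] = sd
            out[f"walking.{side}.normalized.mean.{param}"] = (
                normalize(mean, kind, L) if np.isfinite(mean) else np.nan
            )
            out[f"walking.{side}.normalized.sd.{param}"] = (
                normalize(sd, kind, L) if np.isfinite(sd) else np.nan
            )
        all_speed.extend(
            r["stride_length"] / r["stride_duration"] for r in cycle_rows
        )
    speeds = np.asarray(all_speed, dtype=float)
    mean = float(speeds.mean()) if speeds.size else np.nan
    sd = float(speeds.std(ddof=1)) if speeds.size > 1 else np.nan
    out["walking.overall.raw.mean.walking_speed"] = mean
    out["walking.overall.raw.sd.walking_speed"] = sd
    out["walking.overall.normalized.mean.walking_speed"] = (
        normalize(mean, "speed", L) if np.isfinite(mean) else np.nan
    )
    out["walking.overall.normalized.sd.walking_speed"] = (
        normalize(sd, "speed", L) if np.isfinite(sd) else np.nan
    )
    return out


def assemble_feature_vector(trial, seg, config=None):
    """Full 229-entry feature vector for one trial (see ``emogait.features``)."""
    from .features import extract_trial_features  # local import avoids a cycle

    return extract_trial_features(trial, seg=seg, config=config)
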