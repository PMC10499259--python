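"""Synthetic motion-capture + force-plate study generator.

Emulates the within-subject experiment the analysis assumes: each of the five
emotion conditions (neutral, happy, relaxed, sad, fear) yields one trial per
subject consisting of ~36 s of quiet standing on a force plate (watching the
movie), a two-step gait initiation off the plate, a walk to station A (2 m
from the plate), a 1 s turn, and a walk to station B (stations 4.5 m apart).

The generative model is deliberately simple but fully controlled:

* postural sway — a mean-reverting (Ornstein-Uhlenbeck) COP process per axis
  about a locus, parameterized by stationary SD and time constant;
* weight shifts — Poisson-timed locus jumps with a short constant-velocity
  ramp (new loci kept separated so the ground-truth locus count is
  unambiguous);
* hand gestures — Poisson-timed transient wrist excursions;
* gait — a procedural stepping pattern consistent with the subject's
  GaitParams, with foot lift-off/landing velocities above the pelvis velocity
  so projected-distance extrema coincide with the true contact events;
* emotion effects — per-condition multiplicative deltas on the generative
  sway/posture-variability/gait parameters.

Every trial carries a GroundTruth record (contact events, COP loci,
transition mask, realized parameters) for validating the downstream stages.
Markers and forces are mutually consistent: the COP stays under the feet and
the mean vertical force equals the configured body weight.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .mocap_io import (
    CONDITIONS,
    ForcePlateRecord,
    MarkerTrajectorySet,
    TrialRecording,
)

G = 9.81

GEN_DEFAULTS: dict = {
    "marker_rate": 120.0,
    "force_rate": 1000.0,
    "standing_duration": 36.0,
    "reaction_s": 0.3,
    "station_a_x": 2.0,
    "station_b_x": -2.5,
    "stop_margin": 0.15,
    "turn_pause": 0.2,
    "turn_duration": 1.0,
    "first_step_scale": 0.6,
    "tail_s": 0.4,
    "stop_past_b": 0.35,      # stop point beyond the station-B marker
    "ramp_s": 0.6,            # weight-shift locus ramp
    "shift_lean_front_deg": 3.0,   # frontal trunk lean during a weight shift
    "shift_lean_sag_deg": 2.2,     # sagittal component of the shift lean
    "gesture_lean_sag_deg": 2.5,   # sagittal trunk lean during a hand gesture
    "shift_min_sep": 0.04,    # m between loci
    "marker_noise": 0.001,    # m, white, all markers
    "fz_noise_frac": 0.004,
    "fxy_noise_n": 1.0,
    "trial_jitter": 0.03,     # trial-to-trial CV on generative parameters
    "step_cv": 0.025,         # step-to-step CV of step timing and length
    "bob_amp": 0.012,
    "ml_osc_amp": 0.015,
    "lean_walk_deg": 3.0,
    "heel_z": 0.03,
    "toe_offset": 0.22,
    "arrival_radius": 0.5,
}

EFFECT_PARAMS = (
    "cop_sway_sd_ap",
    "cop_sway_sd_ml",
    "sway_velocity",
    "posture_angle_sd",
    "wrist_hip_distance_sd",
    "step_length",
    "step_duration",
    "weight_shift_rate",
    "gesture_rate",
)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class GaitParams:
    step_length: float          # m
    step_duration: float        # s
    step_width: float           # m
    step_height: float          # m
    double_support_fraction: float  # of the stride, per support
    arm_swing_amplitude: float  # m

    def __post_init__(self) -> None:
        for name in ("step_length", "step_duration", "step_width",
                     "step_height", "arm_swing_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.double_support_fraction < 0.5:
            raise ValueError("double_support_fraction must be in (0, 0.5)")


@dataclass
class StandingParams:
    cop_sway_sd_ap: float = 0.006    # m
    cop_sway_sd_ml: float = 0.0045   # m
    sway_tau: float = 0.25           # s, OU time constant
    posture_angle_sd: float = 0.8    # deg
    wrist_hip_distance_sd: float = 0.008  # m
    weight_shift_rate: float = 2.0 / 30.0  # per s
    gesture_rate: float = 1.0 / 30.0       # per s


@dataclass
class SubjectProfile:
    subject_id: str
    gender: str
    leg_length: float            # m
    stature_scale: float
    mass: float                  # kg
    base_gait: GaitParams
    base_standing: StandingParams

    def __post_init__(self) -> None:
        if not 0.7 <= self.leg_length <= 1.1:
            raise ValueError("leg_length outside [0.7, 1.1] m")
        if self.stature_scale <= 0:
            raise ValueError("stature_scale must be positive")


@dataclass
class EmotionEffectSpec:
    """Per-condition multiplicative deltas on the generative parameters.

    The neutral condition is always the identity; all multipliers must be
    positive so the resulting generative parameters stay positive.
    """

    deltas: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, dd in self.deltas.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            for param, mult in dd.items():
                if param not in EFFECT_PARAMS:
                    raise ValueError(f"unknown effect parameter {param!r}")
                if mult <= 0:
                    raise ValueError("effect multipliers must be positive")
        if any(m != 1.0 for m in self.deltas.get("neutral", {}).values()):
            raise ValueError("neutral condition must map to identity deltas")

    def multiplier(self, condition: str, param: str) -> float:
        return self.deltas.get(condition, {}).get(param, 1.0)

    @classmethod
    def null(cls) -> "EmotionEffectSpec":
        return cls({})

    @classmethod
    def single(cls, param: str, condition: str, mult: float) -> "EmotionEffectSpec":
        return cls({condition: {param: mult}})

    @classmethod
    def moderate(cls) -> "EmotionEffectSpec":
        return cls({
            "happy": {"sway_velocity": 1.25, "gesture_rate": 2.0,
                      "step_duration": 0.95, "cop_sway_sd_ap": 1.15},
            "relaxed": {"cop_sway_sd_ap": 0.8, "cop_sway_sd_ml": 0.8,
                        "sway_velocity": 0.85, "weight_shift_rate": 0.7},
            "sad": {"step_length": 0.92, "step_duration": 1.1,
                    "posture_angle_sd": 1.2, "cop_sway_sd_ml": 1.1,
                    "wrist_hip_distance_sd": 0.9},
            "fear": {"cop_sway_sd_ml": 1.3, "sway_velocity": 1.3,
                     "posture_angle_sd": 1.25, "weight_shift_rate": 1.5,
                     "step_length": 0.95},
        })

    @classmethod
    def strong(cls) -> "EmotionEffectSpec":
        return cls({
            "happy": {"cop_sway_sd_ap": 1.5, "sway_velocity": 1.5,
                      "gesture_rate": 3.0, "step_duration": 0.85},
            "relaxed": {"cop_sway_sd_ap": 0.55, "cop_sway_sd_ml": 0.55,
                        "sway_velocity": 0.6, "weight_shift_rate": 0.4,
                        "step_duration": 1.1},
            "sad": {"step_length": 0.8, "step_duration": 1.25,
                    "posture_angle_sd": 1.6, "wrist_hip_distance_sd": 0.7},
            "fear": {"cop_sway_sd_ml": 1.7, "sway_velocity": 1.6,
                     "posture_angle_sd": 1.5, "weight_shift_rate": 2.5,
                     "step_length": 0.88, "gesture_rate": 2.0},
        })


@dataclass
class GroundTruth:
    """Generator-side annotations used as oracles downstream."""

    heel_strike_times: dict[str, list[float]] = field(default_factory=lambda: {"left": [], "right": []})
    toe_off_times: dict[str, list[float]] = field(default_factory=lambda: {"left": [], "right": []})
    cop_locus_segments: list[tuple[float, float, tuple[float, float]]] = field(default_factory=list)
    transition_intervals: list[tuple[float, float]] = field(default_factory=list)
    transition_mask: np.ndarray | None = None   # marker-rate, standing window
    offload_time: float | None = None
    turn_time: float | None = None
    arrival_time: float | None = None
    gesture_times: list[float] = field(default_factory=list)
    body_weight: float = 0.0
    generative: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode())])


def generate_subject(seed: int, subject_id: str, gender: str) -> SubjectProfile:
    """Deterministic subject profile (anthropometry + baseline parameters)."""
    if gender not in ("female", "male"):
        raise ValueError("gender must be 'female' or 'male'")
    rng = _subject_rng(seed, subject_id)
    leg = float(np.clip(rng.normal(0.89 + (0.03 if gender == "male" else -0.01), 0.04),
                        0.75, 1.05))
    scale = leg / 0.89
    mass = float(np.clip(rng.normal(70.0 if gender == "male" else 60.0, 8.0) * scale,
                         42.0, 110.0))
    gait = GaitParams(
        step_length=float(np.clip(0.78 * leg * (1 + rng.normal(0, 0.05)), 0.45, 0.95)),
        step_duration=float(np.clip(0.55 * np.sqrt(leg / 0.89) * (1 + rng.normal(0, 0.04)),
                                    0.4, 0.75)),
        step_width=float(np.clip(rng.normal(0.11, 0.015), 0.06, 0.18)),
        step_height=float(np.clip(rng.normal(0.05, 0.008), 0.025, 0.09)),
        double_support_fraction=float(np.clip(rng.normal(0.10, 0.015), 0.04, 0.2)),
        arm_swing_amplitude=float(np.clip(rng.normal(0.18, 0.03), 0.08, 0.3)),
    )
    standing = StandingParams(
        cop_sway_sd_ap=float(np.clip(0.006 * np.exp(rng.normal(0, 0.18)), 0.002, 0.015)),
        cop_sway_sd_ml=float(np.clip(0.0045 * np.exp(rng.normal(0, 0.18)), 0.0015, 0.012)),
        sway_tau=0.25,
        posture_angle_sd=float(np.clip(0.8 * np.exp(rng.normal(0, 0.2)), 0.3, 2.0)),
        wrist_hip_distance_sd=float(np.clip(0.008 * np.exp(rng.normal(0, 0.2)), 0.003, 0.02)),
        weight_shift_rate=2.0 / 30.0,
        gesture_rate=1.0 / 30.0,
    )
    return SubjectProfile(subject_id, gender, leg, scale, mass, gait, standing)


def make_subjects(n_subjects: int = 24, n_male: int = 10, seed: int = 0) -> list[SubjectProfile]:
    """Roster with exact gender counts (study default: 24 subjects, 10 male)."""
    rng = np.random.default_rng([seed, 0xABCD])
    genders = ["male"] * n_male + ["female"] * (n_subjects - n_male)
    rng.shuffle(genders)
    return [
        generate_subject(seed, f"S{i + 1:02d}", genders[i]) for i in range(n_subjects)
    ]


def _realize(
    profile: SubjectProfile,
    condition: str,
    effects: EmotionEffectSpec,
    rng: np.random.Generator,
    jitter: float,
) -> tuple[GaitParams, StandingParams]:
    """Apply emotion deltas and trial-to-trial jitter to the baselines."""
    def jit() -> float:
        return float(np.exp(rng.normal(0.0, jitter))) if jitter > 0 else 1.0

    mult = lambda p: effects.multiplier(condition, p)  # noqa: E731
    g = profile.base_gait
    s = profile.base_standing
    vel = mult("sway_velocity")
    gait = GaitParams(
        step_length=g.step_length * mult("step_length") * jit(),
        step_duration=g.step_duration * mult("step_duration") * jit(),
        step_width=g.step_width * jit(),
        step_height=g.step_height * jit(),
        double_support_fraction=g.double_support_fraction,
        arm_swing_amplitude=g.arm_swing_amplitude * jit(),
    )
    standing = StandingParams(
        cop_sway_sd_ap=s.cop_sway_sd_ap * mult("cop_sway_sd_ap") * jit(),
        cop_sway_sd_ml=s.cop_sway_sd_ml * mult("cop_sway_sd_ml") * jit(),
        sway_tau=s.sway_tau / (vel * vel),
        posture_angle_sd=s.posture_angle_sd * mult("posture_angle_sd") * jit(),
        wrist_hip_distance_sd=s.wrist_hip_distance_sd * mult("wrist_hip_distance_sd") * jit(),
        weight_shift_rate=s.weight_shift_rate * mult("weight_shift_rate"),
        gesture_rate=s.gesture_rate * mult("gesture_rate"),
    )
    return gait, standing


# ---------------------------------------------------------------------------
# Low-level stochastic pieces
# ---------------------------------------------------------------------------

def _ou(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (exact discretization)."""
    a = np.exp(-dt / tau)
    s = sd * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    x0 = rng.normal(0.0, sd)
    y, _ = lfilter([1.0], [1.0, -a], s * eps, zi=np.array([a * x0]))
    return y


def _poisson_times(rate: float, t0: float, t1: float, rng: np.random.Generator) -> list[float]:
    times = []
    t = t0
    if rate <= 0:
        return times
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= t1:
            return times
        times.append(t)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def _locus_plan(
    params: StandingParams,
    duration: float,
    rng: np.random.Generator,
    ramp_s: float,
    min_sep: float,
) -> tuple[list[float], list[np.ndarray]]:
    """Weight-shift times and the locus centre after each shift.

    Shifts cycle through a per-trial palette of three well-separated loci
    (centred, left-loaded, right-loaded stance), emulating weight shifts
    between the legs; palette spacing >= ``min_sep`` keeps the ground-truth
    loci unambiguous at any shift rate, and the first two shifts always visit
    distinct loci.
    """
    shifts = _poisson_times(params.weight_shift_rate, 2.0, duration - 2.0 - ramp_s, rng)
    d = rng.uniform(max(min_sep, 0.045), 0.075)
    sign = rng.choice([-1.0, 1.0])
    palette = [
        np.array([rng.uniform(-0.015, 0.015), 0.0]),
        np.array([rng.uniform(-0.015, 0.015), sign * d]),
        np.array([rng.uniform(-0.015, 0.015), -sign * d]),
    ]
    loci = [palette[(k) % 3] for k in range(len(shifts) + 1)]
    return shifts, loci


def _locus_path(
    n: int, rate: float, shifts: list[float], loci: list[np.ndarray], ramp_s: float
) -> np.ndarray:
    t = np.arange(n) / rate
    path = np.tile(loci[0], (n, 1))
    for k, ts in enumerate(shifts):
        w = np.clip((t - ts) / ramp_s, 0.0, 1.0)[:, None]  # constant-velocity ramp
        path = path * (1 - w) + loci[k + 1] * w
    return path


# ---------------------------------------------------------------------------
# Body assembly
# ---------------------------------------------------------------------------

MARKER_NAMES = (
    "HEAD_F", "HEAD_B", "C7", "STERN", "T10", "SACRUM",
    "L_SHOULDER", "L_ELBOW", "L_WRIST", "L_TROCH", "L_KNEE", "L_ANKLE", "L_HEEL", "L_TOE",
    "R_SHOULDER", "R_ELBOW", "R_WRIST", "R_TROCH", "R_KNEE", "R_ANKLE", "R_HEEL", "R_TOE",
)


def _assemble_markers(
    profile: SubjectProfile,
    rate: float,
    pelvis_xy: np.ndarray,       # (n, 2)
    pelvis_dz: np.ndarray,       # (n,)
    phi: np.ndarray,             # (n,) heading angle, rad
    lean_sag: np.ndarray,        # (n,) deg
    lean_front: np.ndarray,      # (n,) deg
    heel: dict[str, np.ndarray],        # side -> (n, 3)
    wrist_extra: dict[str, np.ndarray],  # side -> (n, 3), body frame
    arm_swing: dict[str, np.ndarray],    # side -> (n,) anterior offset
) -> MarkerTrajectorySet:
    n = pelvis_xy.shape[0]
    L = profile.leg_length
    sc = profile.stature_scale
    c, s = np.cos(phi), np.sin(phi)

    def body(ax: np.ndarray | float, ay: np.ndarray | float, az: np.ndarray | float,
             base_xy: np.ndarray, base_z: np.ndarray | float) -> np.ndarray:
        """Offset (ax anterior, ay leftward, az up) in the heading frame."""
        gx = base_xy[:, 0] + ax * c - ay * s
        gy = base_xy[:, 1] + ax * s + ay * c
        return np.column_stack([gx, gy, np.broadcast_to(base_z + az, (n,))])

    hip_z = L + pelvis_dz
    sgn = {"left": 1.0, "right": -1.0}
    m: dict[str, np.ndarray] = {}
    m["SACRUM"] = body(-0.06, 0.0, 0.09, pelvis_xy, hip_z)
    for side in ("left", "right"):
        m[("L_" if side == "left" else "R_") + "TROCH"] = body(
            0.0, sgn[side] * 0.085 * sc, 0.0, pelvis_xy, hip_z
        )

    trunk_len = 0.50 * sc
    sag = np.radians(lean_sag)
    fro = np.radians(lean_front)
    d = np.column_stack([np.sin(sag), np.sin(fro),
                         np.sqrt(np.clip(1 - np.sin(sag) ** 2 - np.sin(fro) ** 2, 0.0, 1.0))])
    # trunk direction expressed in the heading frame
    c7_off = trunk_len * d
    hip_center = np.column_stack([pelvis_xy, hip_z])
    c7 = np.column_stack([
        hip_center[:, 0] + c7_off[:, 0] * c - c7_off[:, 1] * s,
        hip_center[:, 1] + c7_off[:, 0] * s + c7_off[:, 1] * c,
        hip_center[:, 2] + c7_off[:, 2],
    ])
    m["C7"] = c7
    c7_xy = c7[:, :2]
    m["STERN"] = body(0.09 * sc, 0.0, -0.12 * sc, c7_xy, c7[:, 2])
    m["T10"] = body(-0.03 * sc, 0.0, -0.22 * sc, c7_xy, c7[:, 2])
    m["HEAD_F"] = body(0.08, 0.0, 0.18 * sc, c7_xy, c7[:, 2])
    m["HEAD_B"] = body(-0.08, 0.0, 0.18 * sc, c7_xy, c7[:, 2])

    sh_half = 0.19 * sc
    for side in ("left", "right"):
        p = "L_" if side == "left" else "R_"
        g = sgn[side]
        # shoulder line tilts with the frontal lean
        sh = body(0.0, g * sh_half * np.cos(fro), g * sh_half * np.sin(fro), c7_xy, c7[:, 2] - 0.02)
        m[p + "SHOULDER"] = sh
        troch = m[p + "TROCH"]
        wrist_rest = body(
            0.04 + arm_swing[side] + wrist_extra[side][:, 0],
            g * (0.135 * sc) + g * wrist_extra[side][:, 1],
            -0.10 + wrist_extra[side][:, 2],
            troch[:, :2], troch[:, 2],
        )
        m[p + "WRIST"] = wrist_rest
        m[p + "ELBOW"] = (sh + wrist_rest) / 2 + body(
            0.02, g * 0.03, 0.0, np.zeros((n, 2)), 0.0
        )

    toe_off, heelz = 0.22, 0.0
    for side in ("left", "right"):
        p = "L_" if side == "left" else "R_"
        h = heel[side]
        m[p + "HEEL"] = h
        m[p + "TOE"] = np.column_stack([
            h[:, 0] + toe_off * c, h[:, 1] + toe_off * s, h[:, 2] + heelz
        ])
        m[p + "ANKLE"] = np.column_stack([
            h[:, 0] + 0.05 * c, h[:, 1] + 0.05 * s, h[:, 2] + 0.07
        ])
        troch = m[p + "TROCH"]
        ankle = m[p + "ANKLE"]
        m[p + "KNEE"] = (troch + ankle) / 2 + np.column_stack([0.04 * c, 0.04 * s, np.zeros(n)])

    data = {name: m[name] for name in MARKER_NAMES}
    return MarkerTrajectorySet(rate, data)


# ---------------------------------------------------------------------------
# Standing segment
# ---------------------------------------------------------------------------

def _standing_processes(
    profile: SubjectProfile,
    standing: StandingParams,
    n_m: int,
    rate_m: float,
    duration: float,
    rng: np.random.Generator,
    cfg: dict,
    gt: GroundTruth,
) -> dict[str, np.ndarray]:
    """Marker-rate sway, lean, gesture and wrist-noise processes plus the
    force-rate COP path.  Returns a dict of named arrays."""
    dt_m = 1.0 / rate_m
    shifts, loci = _locus_plan(standing, duration, rng, cfg["ramp_s"], cfg["shift_min_sep"])
    t_m = np.arange(n_m) / rate_m

    # force-rate COP
    rate_f = cfg["force_rate"]
    n_f = int(round(duration * rate_f))
    locus_f = _locus_path(n_f, rate_f, shifts, loci, cfg["ramp_s"])
    dev_f = np.column_stack([
        _ou(n_f, 1.0 / rate_f, standing.cop_sway_sd_ap, standing.sway_tau, rng),
        _ou(n_f, 1.0 / rate_f, standing.cop_sway_sd_ml, standing.sway_tau, rng),
    ])
    cop_f = locus_f + dev_f

    # ground truth loci/transitions
    seg_starts = [0.0] + [ts + cfg["ramp_s"] for ts in shifts]
    seg_ends = shifts + [duration]
    gt.cop_locus_segments = [
        (s0, s1, (float(c[0]), float(c[1])))
        for s0, s1, c in zip(seg_starts, seg_ends, loci)
    ]
    gt.transition_intervals = [(ts, ts + cfg["ramp_s"]) for ts in shifts]
    mask = np.zeros(n_m, dtype=bool)
    for a, b in gt.transition_intervals:
        mask[(t_m >= a) & (t_m <= b)] = True
    gt.transition_mask = mask

    # lean and wrist processes (marker rate); gestures
    lean_sag = 2.0 + _ou(n_m, dt_m, standing.posture_angle_sd, 2.0, rng)
    lean_front = _ou(n_m, dt_m, 0.7 * standing.posture_angle_sd, 2.0, rng)
    # weight shifts couple into the trunk: a lean bump toward the new locus
    for (a, b), c_old, c_new in zip(
        gt.transition_intervals, loci[:-1], loci[1:]
    ):
        win = (t_m >= a) & (t_m <= b)
        bump = np.zeros(n_m)
        bump[win] = np.sin(np.pi * (t_m[win] - a) / max(b - a, 1e-6))
        direction = np.sign(c_new[1] - c_old[1]) or 1.0
        lean_front = lean_front + cfg["shift_lean_front_deg"] * direction * bump
        lean_sag = lean_sag + cfg["shift_lean_sag_deg"] * bump
    wsd = standing.wrist_hip_distance_sd / np.sqrt(3)
    wrist_noise = {
        side: np.column_stack([_ou(n_m, dt_m, wsd, 1.0, rng) for _ in range(3)])
        for side in ("left", "right")
    }
    gestures = _poisson_times(standing.gesture_rate, 1.0, duration - 3.0, rng)
    gt.gesture_times = list(gestures)
    bump_amp = np.array([0.10, -0.05, 0.30])
    for tg in gestures:
        side = "left" if rng.random() < 0.5 else "right"
        rise = _smoothstep((t_m - tg) / 0.4)
        fall = _smoothstep((tg + 1.6 + 0.4 - t_m) / 0.4)
        bump = np.minimum(rise, fall)
        wrist_noise[side] = wrist_noise[side] + bump[:, None] * bump_amp[None, :]
        # raising a hand leans the trunk slightly forward
        lean_sag = lean_sag + cfg["gesture_lean_sag_deg"] * bump

    cop_m = np.column_stack([
        np.interp(t_m, np.arange(n_f) / rate_f, cop_f[:, 0]),
        np.interp(t_m, np.arange(n_f) / rate_f, cop_f[:, 1]),
    ])
    return {
        "cop_f": cop_f,
        "cop_m": cop_m,
        "lean_sag": lean_sag,
        "lean_front": lean_front,
        "wrist_noise_left": wrist_noise["left"],
        "wrist_noise_right": wrist_noise["right"],
    }


def _force_record(
    cop_f: np.ndarray,
    body_weight: float,
    rate_f: float,
    rng: np.random.Generator,
    cfg: dict,
    load: np.ndarray | None = None,
) -> ForcePlateRecord:
    n = cop_f.shape[0]
    if load is None:
        load = np.ones(n)
    fz = body_weight * load + body_weight * cfg["fz_noise_frac"] * rng.standard_normal(n)
    fx = cfg["fxy_noise_n"] * rng.standard_normal(n)
    fy = cfg["fxy_noise_n"] * rng.standard_normal(n)
    mx = cop_f[:, 1] * fz
    my = -cop_f[:, 0] * fz
    mz = 0.01 * rng.standard_normal(n)
    return ForcePlateRecord(
        rate=rate_f,
        forces=np.column_stack([fx, fy, fz]),
        moments=np.column_stack([mx, my, mz]),
        z0=0.0,
    )


def generate_standing_segment(
    profile: SubjectProfile,
    condition: str,
    effects: EmotionEffectSpec,
    duration: float = 36.0,
    seed: int = 0,
    config: dict | None = None,
) -> tuple[MarkerTrajectorySet, ForcePlateRecord, GroundTruth]:
    """Quiet standing on the plate: sway, weight shifts, gestures."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    cfg = dict(GEN_DEFAULTS)
    cfg.update(config or {})
    rng = np.random.default_rng([seed, zlib.crc32(profile.subject_id.encode()),
                                 CONDITIONS.index(condition)])
    gait, standing = _realize(profile, condition, effects, rng, cfg["trial_jitter"])
    gt = GroundTruth(body_weight=profile.mass * G,
                     generative={"gait": gait, "standing": standing})
    rate_m = cfg["marker_rate"]
    n_m = int(round(duration * rate_m))
    proc = _standing_processes(profile, standing, n_m, rate_m, duration, rng, cfg, gt)

    pelvis_xy = proc["cop_m"] * 0.9
    w0 = gait.step_width
    heel = {}
    for side, y in (("left", w0 / 2), ("right", -w0 / 2)):
        h = np.tile(np.array([-0.02, y, cfg["heel_z"]]), (n_m, 1))
        heel[side] = h
    zero = np.zeros(n_m)
    markers = _assemble_markers(
        profile, rate_m, pelvis_xy, zero, zero,
        proc["lean_sag"], proc["lean_front"], heel,
        {"left": proc["wrist_noise_left"], "right": proc["wrist_noise_right"]},
        {"left": zero, "right": zero},
    )
    if cfg["marker_noise"] > 0:
        for arr in markers.data.values():
            arr += rng.normal(0.0, cfg["marker_noise"], arr.shape)
    fp = _force_record(proc["cop_f"], gt.body_weight, cfg["force_rate"], rng, cfg)
    return markers, fp, gt


# ---------------------------------------------------------------------------
# Full trial
# ---------------------------------------------------------------------------

@dataclass
class _Swing:
    side: str
    t_to: float
    t_hs: float
    frm: np.ndarray   # (2,)
    to: np.ndarray    # (2,)
    height: float


def _plan_steps(
    gait: GaitParams, t_first_to: float, feet: dict[str, np.ndarray],
    direction: float, target_x: float, first_scale: float,
    rng: np.random.Generator | None = None, step_cv: float = 0.0,
) -> tuple[list[_Swing], float]:
    """Alternating-step plan toward ``target_x``; returns swings and the time
    of the last heel strike.

    ``step_cv`` injects the step-to-step variability of human gait (stride
    time/length CVs of a few percent) as lognormal jitter on each step's
    timing, length and height, plus lateral placement noise.
    """
    T = gait.step_duration
    dsf = gait.double_support_fraction
    w = gait.step_width
    side = "right"
    t = t_first_to
    swings: list[_Swing] = []
    first = True

    def jit(cv: float) -> float:
        if step_cv <= 0 or rng is None:
            return 1.0
        return float(np.exp(rng.normal(0.0, cv)))

    def y_jit() -> float:
        if step_cv <= 0 or rng is None:
            return 0.0
        return float(rng.normal(0.0, 0.008))

    while True:
        opp = "left" if side == "right" else "right"
        T_k = T * jit(step_cv)
        swing_dur = T_k * (1 - 2 * dsf)
        ds = 2 * T_k * dsf
        step = gait.step_length * (first_scale if first else 1.0) * jit(step_cv)
        first = False
        x_next = feet[opp][0] + direction * step
        closing = direction * (x_next - target_x) >= 0
        if closing:
            x_next = target_x
        y_next = (1.0 if side == "left" else -1.0) * (w / 2) * (
            1.0 if direction > 0 else -1.0
        ) + y_jit()
        to_pos = np.array([x_next, y_next])
        sw = _Swing(side, t, t + swing_dur, feet[side][:2].copy(), to_pos,
                    gait.step_height * jit(2 * step_cv))
        swings.append(sw)
        feet[side] = to_pos
        t_hs = sw.t_hs
        t = t_hs + ds
        side = opp
        if closing:
            # trailing foot closes up beside the leading one
            y_close = (1.0 if side == "left" else -1.0) * (w / 2) * (
                1.0 if direction > 0 else -1.0
            )
            sw2 = _Swing(side, t, t + swing_dur, feet[side][:2].copy(),
                         np.array([target_x, y_close]), gait.step_height * 0.8)
            swings.append(sw2)
            feet[side] = sw2.to
            return swings, sw2.t_hs


def _hermite(tau: np.ndarray, m: float) -> np.ndarray:
    """Cubic with s(0)=0, s(1)=1, s'(0)=s'(1)=m (normalized slopes)."""
    h = 3 * tau**2 - 2 * tau**3
    corr = m * (tau - 2 * tau**2 + tau**3) + m * (tau**3 - tau**2)
    return h + corr


def _sample_feet(
    swings: list[_Swing], start: dict[str, np.ndarray], n: int, rate: float,
    heel_z: float, slope: float,
) -> dict[str, np.ndarray]:
    t = np.arange(n) / rate
    out = {}
    for side in ("left", "right"):
        xy = np.tile(start[side][:2], (n, 1))
        z = np.full(n, heel_z)
        for sw in [s for s in swings if s.side == side]:
            i0 = int(np.ceil(sw.t_to * rate))
            i1 = int(np.floor(sw.t_hs * rate))
            if i1 > i0:
                tau = (t[i0:i1 + 1] - sw.t_to) / (sw.t_hs - sw.t_to)
                s_prof = _hermite(tau, slope)
                xy[i0:i1 + 1] = sw.frm + s_prof[:, None] * (sw.to - sw.frm)
                z[i0:i1 + 1] = heel_z + sw.height * np.sin(np.pi * tau)
            xy[i1 + 1:] = sw.to
            z[i1 + 1:] = heel_z
        out[side] = np.column_stack([xy, z])
    return out


def generate_trial(
    profile: SubjectProfile,
    condition: str,
    effects: EmotionEffectSpec,
    seed: int = 0,
    config: dict | None = None,
) -> tuple[TrialRecording, GroundTruth]:
    """One full session: standing -> initiation -> walk to A -> turn -> walk
    toward B (trial ends just after arrival)."""
    cfg = dict(GEN_DEFAULTS)
    cfg.update(config or {})
    rng = np.random.default_rng([seed, zlib.crc32(profile.subject_id.encode()),
                                 CONDITIONS.index(condition), 7])
    gait, standing = _realize(profile, condition, effects, rng, cfg["trial_jitter"])
    gt = GroundTruth(body_weight=profile.mass * G,
                     generative={"gait": gait, "standing": standing})

    rate_m, rate_f = cfg["marker_rate"], cfg["force_rate"]
    t_stand = cfg["standing_duration"]
    t_go = t_stand + cfg["reaction_s"]
    w0 = gait.step_width
    feet = {
        "left": np.array([-0.02, w0 / 2]),
        "right": np.array([-0.02, -w0 / 2]),
    }
    start_feet = {k: v.copy() for k, v in feet.items()}

    # --- step plans ---------------------------------------------------------
    xa = cfg["station_a_x"] - cfg["stop_margin"]
    swings1, t_end1 = _plan_steps(
        gait, t_go, feet, +1.0, xa, cfg["first_step_scale"],
        rng=rng, step_cv=cfg["step_cv"],
    )
    t_turn0 = t_end1 + cfg["turn_pause"]
    t_turn1 = t_turn0 + cfg["turn_duration"]
    # participants stop at the seat just past the station-B marker, so full
    # gait cycles continue through the trim point
    swings2, t_end2 = _plan_steps(
        gait, t_turn1 + cfg["turn_pause"], feet, -1.0,
        cfg["station_b_x"] - cfg["stop_past_b"], 0.7,
        rng=rng, step_cv=cfg["step_cv"],
    )
    total = t_end2 + cfg["tail_s"]
    n_m = int(round(total * rate_m))
    t_m = np.arange(n_m) / rate_m
    swings = swings1 + swings2
    for sw in swings:
        gt.toe_off_times[sw.side].append(sw.t_to)
        gt.heel_strike_times[sw.side].append(sw.t_hs)
    gt.turn_time = t_turn1

    # --- standing processes -------------------------------------------------
    proc = _standing_processes(
        profile, standing, n_m, rate_m, t_stand, rng, cfg, gt
    )
    # pad marker-rate standing processes to the full trial
    def pad(x: np.ndarray) -> np.ndarray:
        n_s = x.shape[0]
        if x.ndim == 1:
            return np.concatenate([x, np.full(n_m - n_s, x[-1])])
        return np.vstack([x, np.tile(x[-1], (n_m - n_s, 1))])

    n_s = proc["cop_m"].shape[0]
    lean_sag = pad(proc["lean_sag"])
    lean_front = pad(proc["lean_front"])
    wrist_noise = {
        "left": pad(proc["wrist_noise_left"]),
        "right": pad(proc["wrist_noise_right"]),
    }

    # --- feet, pelvis, heading ---------------------------------------------
    # foot lift-off/landing speed ~2x the pelvis speed: the projected-distance
    # corner at each contact is then symmetric, so zero-phase smoothing does
    # not displace its extremum
    dsf = gait.double_support_fraction
    slope = 1.0 - 2 * dsf
    heel = _sample_feet(swings, start_feet, n_m, rate_m, cfg["heel_z"], slope)

    anchors_t = [t_go]
    anchors_x = [0.0]
    pos = {k: v[:2].copy() for k, v in start_feet.items()}
    for sw in sorted(swings, key=lambda s: s.t_hs):
        pos[sw.side] = sw.to
        anchors_t.append(sw.t_hs)
        anchors_x.append((pos["left"][0] + pos["right"][0]) / 2)
    pchip_t = np.array(anchors_t)
    pchip_x = np.array(anchors_x)
    # insert flat anchors at the turn and at the end
    ins = np.searchsorted(pchip_t, t_turn0)
    pchip_t = np.insert(pchip_t, ins, [t_turn0, t_turn1])
    x_hold = pchip_x[ins - 1]
    pchip_x = np.insert(pchip_x, ins, [x_hold, x_hold])
    pchip_t = np.append(pchip_t, total + 0.01)
    pchip_x = np.append(pchip_x, pchip_x[-1])
    pelvis_walk = PchipInterpolator(pchip_t, pchip_x)(np.clip(t_m, t_go, None))
    pelvis_walk[t_m < t_go] = 0.0

    fade = np.clip((t_go + 0.5 - t_m) / 1.0, 0.0, 1.0)
    sway_xy = proc["cop_m"] * 0.9
    sway_xy = pad(sway_xy)
    T = gait.step_duration
    vx = np.gradient(pelvis_walk) * rate_m
    env = np.clip(np.abs(vx) / max(0.3, gait.step_length / T * 0.7), 0.0, 1.0)
    pelvis_x = pelvis_walk + sway_xy[:, 0] * fade
    pelvis_y = sway_xy[:, 1] * fade + cfg["ml_osc_amp"] * env * np.sin(np.pi * t_m / T)
    pelvis_xy = np.column_stack([pelvis_x, pelvis_y])
    pelvis_dz = -cfg["bob_amp"] * env * (0.5 - 0.5 * np.cos(2 * np.pi * t_m / T))

    phi = np.where(t_m >= t_turn1, np.pi, 0.0)
    in_turn = (t_m >= t_turn0) & (t_m < t_turn1)
    phi[in_turn] = np.pi * _smoothstep((t_m[in_turn] - t_turn0) / cfg["turn_duration"])

    lean_sag = lean_sag + cfg["lean_walk_deg"] * env
    arm = {}
    for side, ph in (("left", 0.0), ("right", np.pi)):
        arm[side] = gait.arm_swing_amplitude * env * np.sin(2 * np.pi * t_m / (2 * T) + ph)

    markers = _assemble_markers(
        profile, rate_m, pelvis_xy, pelvis_dz, phi, lean_sag, lean_front,
        heel, wrist_noise, arm,
    )
    if cfg["marker_noise"] > 0:
        for arr in markers.data.values():
            arr += rng.normal(0.0, cfg["marker_noise"], arr.shape)

    # --- force plate --------------------------------------------------------
    n_f = int(round(total * rate_f))
    t_f = np.arange(n_f) / rate_f
    cop_stand = proc["cop_f"]
    cop_full = np.vstack([cop_stand, np.tile(cop_stand[-1], (n_f - cop_stand.shape[0], 1))])
    first_sw = swings1[0]
    second_sw = swings1[1]
    load = np.ones(n_f)
    # full weight until the first landing off the plate, then transfer
    hs1, to2 = first_sw.t_hs, second_sw.t_to
    seg = (t_f >= hs1) & (t_f < to2)
    load[seg] = 1.0 - 0.55 * (t_f[seg] - hs1) / max(to2 - hs1, 1e-6)
    seg2 = (t_f >= to2) & (t_f < to2 + 0.15)
    load[seg2] = 0.45 * (1.0 - (t_f[seg2] - to2) / 0.15)
    load[t_f >= to2 + 0.15] = 0.0
    gt.offload_time = hs1 + (0.5 / 0.55) * (to2 - hs1)
    fp = _force_record(cop_full, gt.body_weight, rate_f, rng, cfg, load=load)

    # arrival at station B: first frame the sacrum marker (the trim reference)
    # is within the trim radius
    bx = cfg["station_b_x"]
    sac = markers.data["SACRUM"]
    inside = np.flatnonzero(np.hypot(sac[:, 0] - bx, sac[:, 1]) <= cfg["arrival_radius"])
    gt.arrival_time = float(inside[0] / rate_m) if inside.size else None

    trial = TrialRecording(
        subject_id=profile.subject_id,
        gender=profile.gender,
        condition=condition,
        markers=markers,
        forceplate=fp,
        annotations={"seed": seed, "condition": condition},
    )
    return trial, gt


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

DEFAULT_DROPPED = 3 * ["relaxed"] + ["fear"]  # paper-matching exclusion counts


@dataclass
class StudyDataset:
    """Lazy study: trial plan plus generation parameters.

    Trials are generated on demand (``iter_trials``) to keep memory flat for
    the full 24-subject design.
    """

    subjects: list[SubjectProfile]
    effects: EmotionEffectSpec
    seed: int
    dropped_trials: list[tuple[str, str]]
    config: dict = field(default_factory=dict)

    @property
    def trial_plan(self) -> list[tuple[str, str]]:
        dropped = set(self.dropped_trials)
        return [
            (p.subject_id, cond)
            for p in self.subjects
            for cond in CONDITIONS
            if (p.subject_id, cond) not in dropped
        ]

    def profile(self, subject_id: str) -> SubjectProfile:
        for p in self.subjects:
            if p.subject_id == subject_id:
                return p
        raise KeyError(subject_id)

    def iter_trials(self) -> Iterator[tuple[TrialRecording, GroundTruth]]:
        for subject_id, cond in self.trial_plan:
            yield self.generate(subject_id, cond)

    def generate(self, subject_id: str, condition: str) -> tuple[TrialRecording, GroundTruth]:
        return generate_trial(
            self.profile(subject_id), condition, self.effects,
            seed=self.seed, config=self.config,
        )


def generate_study(
    n_subjects: int = 24,
    effects: EmotionEffectSpec | None = None,
    seed: int = 0,
    dropped_trials: list[tuple[str, str]] | str | None = "default",
    n_male: int = 10,
    config: dict | None = None,
) -> StudyDataset:
    """Study with one trial per subject x condition minus the dropped trials.

    ``dropped_trials="default"`` mirrors the study exclusions (3 relaxed + 1
    fear trials, subjects drawn reproducibly from the roster).
    """
    subjects = make_subjects(n_subjects, min(n_male, n_subjects), seed)
    ids = [p.subject_id for p in subjects]
    if dropped_trials == "default":
        rng = np.random.default_rng([seed, 999])
        relaxed = rng.choice(ids, size=min(3, n_subjects), replace=False)
        fear = rng.choice(ids, size=1)
        dropped = [(s, "relaxed") for s in relaxed] + [(str(fear[0]), "fear")]
    else:
        dropped = list(dropped_trials or [])
    for s, cond in dropped:
        if s not in ids:
            raise ValueError(f"dropped trial references unknown subject {s!r}")
        if cond not in CONDITIONS:
            raise ValueError(f"dropped trial references unknown condition {cond!r}")
    return StudyDataset(
        subjects=subjects,
        effects=effects or EmotionEffectSpec.null(),
        seed=seed,
        dropped_trials=dropped,
        config=dict(config or {}),
    )
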