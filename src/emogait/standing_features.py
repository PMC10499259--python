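"""Balance (centre-of-pressure) and posture parameters with transition removal.

People shift their weight and gesture while standing.  To keep sway statistics
from being inflated by those transitions, samples are first grouped into loci
by mean shift; within each locus a density-based pass (DBSCAN) flags
fast-moving, spatially sparse samples as transitions, and the flagged set is
dilated by a short temporal window to bridge the slow shoulders of each
transition ramp.  Statistics are then combined across loci weighted by the
number of samples in each cluster, which measures variability *about* each
locus rather than the locus separation itself.

Every balance/posture parameter is emitted in a "full" (all samples), a
"clustered" (cluster-relative, transition-removed) and a "transition"
(transition samples only) variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from sklearn.cluster import MeanShift
from sklearn.neighbors import KDTree

from .mocap_io import COPSeries, MarkerTrajectorySet

VARIANTS = ("full", "clustered", "transition")

BALANCE_STATS = (
    "sd.ap",
    "sd.ml",
    "range.ap",
    "range.ml",
    "speed_mean.ap",
    "speed_mean.ml",
    "speed_mean.overall",
    "speed_sd.ap",
    "speed_sd.ml",
    "speed_sd.overall",
    "path_length.overall",
    "mean_ratio.xy",
)

POSTURE_CHANNELS = (
    "shoulder_sagittal",
    "shoulder_frontal",
    "back_sagittal",
    "wrist_hip_left",
    "wrist_hip_right",
)

_MIN_GROUP = 10  # samples; smaller groups yield flagged-missing statistics


def _density_noise(pts: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN noise mask without materializing neighbour lists.

    A sample is noise iff it is not a core point (fewer than ``min_samples``
    neighbours within ``eps``, self included) and not within ``eps`` of any
    core point — identical to DBSCAN's noise set for the same parameters.
    """
    tree = KDTree(pts)
    counts = tree.query_radius(pts, r=eps, count_only=True)
    core = counts >= min_samples
    noise = ~core
    if core.any() and noise.any():
        core_tree = KDTree(pts[core])
        near_core = core_tree.query_radius(pts[noise], r=eps, count_only=True) > 0
        idx = np.flatnonzero(noise)
        noise[idx[near_core]] = False
    return noise


@dataclass
class ClusterLabeling:
    """Per-sample locus assignment.

    ``labels``: locus id >= 0, -1 for transition/noise, -2 for invalid input.
    ``centers``: (n_loci, d) locus centres ordered by decreasing sample count.
    """

    labels: np.ndarray
    centers: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.centers.shape[0]

    @property
    def counts(self) -> np.ndarray:
        return np.array([(self.labels == i).sum() for i in range(self.n_loci)])

    @property
    def transition_mask(self) -> np.ndarray:
        return self.labels == -1


def cluster_loci(
    points: np.ndarray,
    bandwidth: float,
    rate: float = 120.0,
    eps: float | None = None,
    min_samples_s: float = 0.25,
    dilate_s: float = 0.25,
    max_fit_points: int = 1500,
) -> ClusterLabeling:
    """Mean-shift loci with a density-based transition pass.

    ``eps`` defaults to bandwidth/4; ``min_samples`` is ``min_samples_s``
    seconds of samples.  Transition labels are dilated by ``dilate_s`` seconds
    to each side so whole ramps are flagged, not only their fast cores.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    valid = np.isfinite(pts).all(axis=1)
    if valid.sum() < _MIN_GROUP:
        raise ValueError(f"need at least {_MIN_GROUP} valid samples")
    vpts = pts[valid]
    stride = max(1, int(np.ceil(vpts.shape[0] / max_fit_points)))
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=True, cluster_all=True)
    ms.fit(vpts[::stride])
    ms_labels = ms.predict(vpts)

    min_samples = max(2, round(min_samples_s * rate))
    if eps is None:
        eps = bandwidth / 4.0
    transition = np.zeros(vpts.shape[0], dtype=bool)
    for cid in np.unique(ms_labels):
        sel = ms_labels == cid
        if sel.sum() < min_samples:
            transition[sel] = True
            continue
        noise = _density_noise(vpts[sel], eps, min_samples)
        idx = np.flatnonzero(sel)
        transition[idx[noise]] = True

    n_dilate = round(dilate_s * rate)
    if n_dilate > 0 and transition.any():
        transition = binary_dilation(transition, np.ones(2 * n_dilate + 1, dtype=bool))

    # rebuild locus ids on the non-transition samples, largest first
    final = np.full(vpts.shape[0], -1, dtype=int)
    keep = ~transition
    centers, order = [], []
    for cid in np.unique(ms_labels):
        sel = keep & (ms_labels == cid)
        if sel.sum() >= min_samples:
            order.append((sel.sum(), cid, vpts[sel].mean(axis=0)))
    order.sort(key=lambda t: -t[0])
    for new_id, (_, cid, centre) in enumerate(order):
        final[keep & (ms_labels == cid)] = new_id
        centers.append(centre)
    labels = np.full(pts.shape[0], -2, dtype=int)
    labels[valid] = final
    return ClusterLabeling(
        labels=labels,
        centers=np.asarray(centers) if centers else np.empty((0, pts.shape[1])),
    )


def weighted_cluster_stats(
    values: np.ndarray, labeling: ClusterLabeling
) -> tuple[float, float]:
    """Count-weighted average of the per-cluster means and SDs.

    The weighted SD averages per-cluster SDs (weights = cluster sample
    counts); it is not inflated by the separation between loci, unlike the
    pooled SD of the concatenated samples.
    """
    values = np.asarray(values, dtype=float)
    total = 0
    wm = ws = 0.0
    for cid in range(labeling.n_loci):
        v = values[labeling.labels == cid]
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        total += v.size
        wm += v.size * v.mean()
        ws += v.size * v.std()
    if total == 0:
        raise ValueError("no non-transition samples")
    return wm / total, ws / total


# ---------------------------------------------------------------------------
# Balance (COP) features
# ---------------------------------------------------------------------------

def _grouped_indices(labeling: ClusterLabeling, variant: str) -> list[np.ndarray]:
    labels = labeling.labels
    if variant == "full":
        return [np.flatnonzero(labels >= -1)]
    if variant == "clustered":
        return [np.flatnonzero(labels == i) for i in range(labeling.n_loci)]
    if variant == "transition":
        return [np.flatnonzero(labels == -1)]
    raise ValueError(f"unknown variant {variant!r}")


def _run_velocity(xy: np.ndarray, member: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference velocity at samples whose neighbours are in-group."""
    ok = member[:-2] & member[1:-1] & member[2:]
    v = (xy[2:] - xy[:-2]) * (rate / 2.0)
    return v[ok]


def _group_stats(xy: np.ndarray, groups: list[np.ndarray], rate: float) -> dict[str, float]:
    n_total = sum(g.size for g in groups)
    out = {s: np.nan for s in BALANCE_STATS}
    if n_total < _MIN_GROUP:
        return out
    member_any = np.zeros(xy.shape[0], dtype=bool)
    acc = {s: 0.0 for s in BALANCE_STATS if s != "mean_ratio.xy"}
    abs_dev = np.zeros(2)
    path = 0.0
    for g in groups:
        if g.size == 0:
            continue
        member = np.zeros(xy.shape[0], dtype=bool)
        member[g] = True
        member_any |= member
        pts = xy[g]
        dev = pts - pts.mean(axis=0)
        w = g.size / n_total
        acc["sd.ap"] += w * dev[:, 0].std()
        acc["sd.ml"] += w * dev[:, 1].std()
        acc["range.ap"] += w * float(np.ptp(pts[:, 0]))
        acc["range.ml"] += w * float(np.ptp(pts[:, 1]))
        abs_dev += w * np.abs(dev).mean(axis=0)
        v = _run_velocity(xy, member, rate)
        if v.shape[0] >= 2:
            speed = np.hypot(v[:, 0], v[:, 1])
            acc["speed_mean.ap"] += w * np.abs(v[:, 0]).mean()
            acc["speed_mean.ml"] += w * np.abs(v[:, 1]).mean()
            acc["speed_mean.overall"] += w * speed.mean()
            acc["speed_sd.ap"] += w * np.abs(v[:, 0]).std()
            acc["speed_sd.ml"] += w * np.abs(v[:, 1]).std()
            acc["speed_sd.overall"] += w * speed.std()
        pair = member[:-1] & member[1:]
        seg = np.sqrt(((xy[1:] - xy[:-1]) ** 2).sum(axis=1))
        path += seg[pair].sum()
    out.update(acc)
    out["path_length.overall"] = path
    out["mean_ratio.xy"] = abs_dev[0] / abs_dev[1] if abs_dev[1] > 0 else np.nan
    return out


def balance_features(
    cop: COPSeries, labeling: ClusterLabeling, min_window_s: float = 5.0
) -> dict[str, float]:
    """Named COP sway parameters in all three variants.

    Keys follow ``balance.standing.<variant>.<stat>.<axis>``.
    """
    if cop.n_samples / cop.rate < min_window_s:
        raise ValueError(f"standing window shorter than {min_window_s} s")
    xy = cop.xy
    out: dict[str, float] = {}
    for variant in VARIANTS:
        groups = _grouped_indices(labeling, variant)
        stats = _group_stats(xy, groups, cop.rate)
        for key, val in stats.items():
            out[f"balance.standing.{variant}.{key}"] = val
    out["balance.standing.clustered.n_loci.count"] = float(labeling.n_loci)
    return out


# ---------------------------------------------------------------------------
# Posture angles and distances
# ---------------------------------------------------------------------------

@dataclass
class AngleSeries:
    """Upper-body angle series (degrees) and wrist-to-hip distances (m)."""

    rate: float
    channels: dict[str, np.ndarray]

    def window(self, t0: float, t1: float) -> "AngleSeries":
        i0 = max(0, int(np.ceil(t0 * self.rate - 1e-9)))
        i1 = int(np.floor(t1 * self.rate + 1e-9))
        return AngleSeries(self.rate, {k: v[i0:i1] for k, v in self.channels.items()})


def posture_angles(m: MarkerTrajectorySet) -> AngleSeries:
    """Shoulder/back inclinations (anatomical planes) and wrist-hip distances.

    * shoulder_sagittal: mid-shoulder -> mid-hip segment from vertical,
      projected on the sagittal (X-Z) plane, degrees;
    * shoulder_frontal: left-right shoulder line tilt from horizontal,
      frontal (Y-Z) projection;
    * back_sagittal: C7 -> sacrum trunk inclination, sagittal projection;
    * wrist_hip_left/right: Euclidean wrist to ipsilateral trochanter.
    """
    required = ("L_SHOULDER", "R_SHOULDER", "L_TROCH", "R_TROCH", "C7", "SACRUM",
                "L_WRIST", "R_WRIST")
    for name in required:
        if name not in m.data:
            raise ValueError(f"required marker {name!r} absent")
    d = m.data
    mid_sh = (d["L_SHOULDER"] + d["R_SHOULDER"]) / 2
    mid_hip = (d["L_TROCH"] + d["R_TROCH"]) / 2
    trunk = mid_sh - mid_hip
    back = d["C7"] - d["SACRUM"]
    sh_line = d["L_SHOULDER"] - d["R_SHOULDER"]
    channels = {
        "shoulder_sagittal": np.degrees(np.arctan2(trunk[:, 0], trunk[:, 2])),
        "shoulder_frontal": np.degrees(np.arctan2(sh_line[:, 2], np.abs(sh_line[:, 1]))),
        "back_sagittal": np.degrees(np.arctan2(back[:, 0], back[:, 2])),
        "wrist_hip_left": np.linalg.norm(d["L_WRIST"] - d["L_TROCH"], axis=1),
        "wrist_hip_right": np.linalg.norm(d["R_WRIST"] - d["R_TROCH"], axis=1),
    }
    return AngleSeries(m.rate, channels)


_CHANNEL_BANDWIDTH = {
    "shoulder_sagittal": 2.0,   # degrees
    "shoulder_frontal": 2.0,
    "back_sagittal": 2.0,
    "wrist_hip_left": 0.05,     # metres
    "wrist_hip_right": 0.05,
}


def _variant_stats(values: np.ndarray, labeling: ClusterLabeling) -> dict[str, tuple]:
    res = {}
    finite = values[np.isfinite(values)]
    res["full"] = (
        (finite.mean(), finite.std()) if finite.size >= _MIN_GROUP else (np.nan, np.nan)
    )
    try:
        res["clustered"] = weighted_cluster_stats(values, labeling)
    except ValueError:
        res["clustered"] = (np.nan, np.nan)
    tr = values[labeling.transition_mask]
    tr = tr[np.isfinite(tr)]
    res["transition"] = (
        (tr.mean(), tr.std()) if tr.size >= _MIN_GROUP else (np.nan, np.nan)
    )
    return res


def posture_features(
    m: MarkerTrajectorySet,
    phase: str,
    cop_labeling: ClusterLabeling | None = None,
    bandwidths: dict[str, float] | None = None,
    cluster_kwargs: dict | None = None,
) -> dict[str, float]:
    """Mean/SD of each posture channel in full/clustered/transition variants.

    ``phase`` is "standing" or "walking" (key prefix).  For standing, base of
    support and step width (inter-ankle and COP-locus based) are added.
    """
    angles = posture_angles(m)
    bw = dict(_CHANNEL_BANDWIDTH)
    bw.update(bandwidths or {})
    prefix = "posture.standing" if phase == "standing" else "walking_posture"
    out: dict[str, float] = {}
    for ch in POSTURE_CHANNELS:
        values = angles.channels[ch]
        try:
            labeling = cluster_loci(values, bw[ch], rate=m.rate, **(cluster_kwargs or {}))
        except ValueError:
            labeling = ClusterLabeling(
                labels=np.full(values.shape[0], -2), centers=np.empty((0, 1))
            )
        stats = _variant_stats(values, labeling)
        for variant, (mean, sd) in stats.items():
            out[f"{prefix}.{variant}.mean.{ch}"] = mean
            out[f"{prefix}.{variant}.sd.{ch}"] = sd
    if phase == "standing":
        out.update(_standing_support_features(m, cop_labeling))
    return out


def _standing_support_features(
    m: MarkerTrajectorySet, cop_labeling: ClusterLabeling | None
) -> dict[str, float]:
    d = m.data
    out: dict[str, float] = {}
    width = np.abs(d["L_ANKLE"][:, 1] - d["R_ANKLE"][:, 1])
    out["posture.standing.full.mean.step_width_ankles"] = float(np.nanmean(width))
    out["posture.standing.full.sd.step_width_ankles"] = float(np.nanstd(width))
    bos = np.linalg.norm(d["L_HEEL"][:, :2] - d["R_HEEL"][:, :2], axis=1)
    out["posture.standing.full.mean.base_of_support"] = float(np.nanmean(bos))
    out["posture.standing.full.sd.base_of_support"] = float(np.nanstd(bos))
    mean = sd = np.nan
    if cop_labeling is not None and cop_labeling.n_loci >= 2:
        ml = cop_labeling.centers[:, 1]
        counts = cop_labeling.counts.astype(float)
        mean = float(np.ptp(ml))
        wmean = (counts * ml).sum() / counts.sum()
        sd = float(np.sqrt((counts * (ml - wmean) ** 2).sum() / counts.sum()))
    out["posture.standing.clustered.mean.step_width_cop"] = mean
    out["posture.standing.clustered.sd.step_width_cop"] = sd
    return out
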