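"""Per-trial feature extraction: the full 229-parameter vector.

``extract_trial_features`` runs the processing chain on one trial — gap fill,
zero-phase filtering, force/marker synchronization, phase segmentation, COP
clustering — and returns a pandas Series indexed by the registry names.
Features whose phase is absent (e.g. a trial without walking) are flagged
missing (NaN), never silently zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import gait_features, preprocess, registry, standing_features
from .mocap_io import TrialRecording, cop_from_forceplate, synchronize
from .preprocess import PhaseSegmentation, SegmentationError

DEFAULT_EXTRACTION = {
    "marker_cutoff_hz": 10.0,
    "force_cutoff_hz": 20.0,
    "max_gap_frames": 100,
    "standing_window_s": 30.0,
    "offload_guard_s": 5.0,
    "cop_bandwidth_m": 0.02,
    "contact_threshold_n": 20.0,
    "trim": True,
    "station_b": (-2.5, 0.0),
    "trim_radius_m": 0.5,
    "trim_offset_s": 0.5,
}


def extract_trial_features(
    trial: TrialRecording,
    seg: PhaseSegmentation | None = None,
    config: dict | None = None,
) -> pd.Series:
    """229 named motion parameters for one trial (NaN where unavailable)."""
    cfg = dict(DEFAULT_EXTRACTION)
    cfg.update(config or {})
    names = registry.feature_names()
    values = pd.Series(np.nan, index=pd.Index(names, name="feature"), dtype=float)

    markers = preprocess.fill_gaps(trial.markers, max_gap=cfg["max_gap_frames"])
    trial = TrialRecording(
        trial.subject_id, trial.gender, trial.condition,
        markers, trial.forceplate, trial.annotations,
    )
    trial = preprocess.filter_trial(
        trial, marker_cutoff=cfg["marker_cutoff_hz"], force_cutoff=cfg["force_cutoff_hz"]
    )
    if cfg["trim"]:
        try:
            trial = preprocess.trim_trial(
                trial, tuple(cfg["station_b"]),
                radius=cfg["trim_radius_m"], offset=cfg["trim_offset_s"],
            )
        except ValueError:
            pass  # e.g. standing-only trials never reach station B
    fp = synchronize(trial.forceplate, trial.markers.rate)

    if seg is None:
        try:
            seg = preprocess.segment_phases(
                trial,
                standing_window_s=cfg["standing_window_s"],
                offload_guard_s=cfg["offload_guard_s"],
            )
        except SegmentationError as exc:
            warnings.warn(f"trial degraded to standing-only: {exc}", stacklevel=2)
            seg = None

    standing = seg.standing_window if seg is not None else (0.0, cfg["standing_window_s"])

    # --- balance + standing posture ---------------------------------------
    cop_labeling = None
    try:
        cop = cop_from_forceplate(fp, contact_threshold=cfg["contact_threshold_n"])
        i0 = int(np.ceil(standing[0] * cop.rate))
        i1 = int(np.floor(standing[1] * cop.rate))
        from .mocap_io import COPSeries

        cop_w = COPSeries(cop.rate, cop.xy[i0:i1], cop.valid[i0:i1])
        cop_labeling = standing_features.cluster_loci(
            cop_w.xy, bandwidth=cfg["cop_bandwidth_m"], rate=cop_w.rate
        )
        values.update(pd.Series(standing_features.balance_features(cop_w, cop_labeling)))
    except ValueError as exc:
        warnings.warn(f"balance features unavailable: {exc}", stacklevel=2)

    try:
        stand_markers = trial.markers.window(*standing)
        values.update(
            pd.Series(
                standing_features.posture_features(
                    stand_markers, phase="standing", cop_labeling=cop_labeling
                )
            )
        )
    except ValueError as exc:
        warnings.warn(f"standing posture features unavailable: {exc}", stacklevel=2)

    if seg is None:
        return values

    # --- gait initiation + walking ----------------------------------------
    L = gait_features.leg_length_estimate(trial.markers, standing)
    try:
        values.update(
            pd.Series(
                gait_features.gait_initiation_features(
                    trial.markers, seg.initiation_steps, seg.events, L,
                    standing_window=standing,
                )
            )
        )
    except ValueError as exc:
        warnings.warn(f"gait-initiation features unavailable: {exc}", stacklevel=2)

    values.update(
        pd.Series(
            gait_features.walking_features(
                trial.markers, seg.walking_cycles, seg.events, L,
                t_start=seg.turn_time,
            )
        )
    )

    if seg.turn_time is not None:
        walk_markers = trial.markers.window(
            seg.turn_time, trial.markers.n_frames / trial.markers.rate
        )
        try:
            values.update(
                pd.Series(standing_features.posture_features(walk_markers, phase="walking"))
            )
        except ValueError as exc:
            warnings.warn(f"walking posture features unavailable: {exc}", stacklevel=2)
    return values


META_COLUMNS = ("subject_id", "gender", "condition")


def extract_study_features(study, config: dict | None = None) -> pd.DataFrame:
    """Feature table for a whole (lazy) synthetic study.

    Trials are generated and reduced one at a time so memory stays flat for
    the full 24-subject design.
    """
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for trial, _gt in study.iter_trials():
            feats = extract_trial_features(trial, config=config)
            rec = {
                "subject_id": trial.subject_id,
                "gender": trial.gender,
                "condition": trial.condition,
            }
            rec.update(feats.to_dict())
            records.append(rec)
    df = pd.DataFrame(records)
    return df[list(META_COLUMNS) + registry.feature_names()]


def build_feature_table(rows: list[tuple[TrialRecording, pd.Series]]) -> pd.DataFrame:
    """Trials x (metadata + 229 features) table; one row per trial."""
    records = []
    for trial, feats in rows:
        rec = {
            "subject_id": trial.subject_id,
            "gender": trial.gender,
            "condition": trial.condition,
        }
        rec.update(feats.to_dict())
        records.append(rec)
    df = pd.DataFrame(records)
    ordered = list(META_COLUMNS) + registry.feature_names()
    return df[ordered]
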