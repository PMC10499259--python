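"""Pipeline orchestration: simulate -> extract -> stats -> classify.

Each stage is a plain function over artifacts (study manifest, feature CSV,
stats CSV, classification reports) and is runnable standalone; ``run_pipeline``
chains them, collecting timings and warnings into a JSON run manifest.  Given
fixed seeds every stage is deterministic, so re-running a stage on unchanged
inputs reproduces its outputs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, emoclassify, emostats, features, synthcap
from .config import config_hash, default_config

log = logging.getLogger("emogait")


def _effects_from_config(spec) -> synthcap.EmotionEffectSpec:
    if spec in (None, "null"):
        return synthcap.EmotionEffectSpec.null()
    if spec == "moderate":
        return synthcap.EmotionEffectSpec.moderate()
    if spec == "strong":
        return synthcap.EmotionEffectSpec.strong()
    if isinstance(spec, dict):
        return synthcap.EmotionEffectSpec(spec)
    raise ValueError(f"unknown effects spec {spec!r}")


def build_study(cfg: dict) -> synthcap.StudyDataset:
    g = cfg["generator"]
    return synthcap.generate_study(
        n_subjects=g["n_subjects"],
        effects=_effects_from_config(g.get("effects")),
        seed=cfg["seed"],
        dropped_trials=g.get("dropped_trials", "default"),
        n_male=g.get("n_male", 10),
        config=g.get("overrides", {}),
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path, write_trials: bool = False) -> synthcap.StudyDataset:
    """Materialize the study plan (and optionally the raw trial files)."""
    study = build_study(cfg)
    manifest = {
        "seed": study.seed,
        "n_subjects": len(study.subjects),
        "conditions": list(synthcap.CONDITIONS),
        "dropped_trials": study.dropped_trials,
        "n_trials": len(study.trial_plan),
        "subjects": [
            {"subject_id": p.subject_id, "gender": p.gender,
             "leg_length": p.leg_length, "mass": p.mass}
            for p in study.subjects
        ],
        "generator_overrides": study.config,
    }
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "study_manifest.json").write_text(json.dumps(manifest, indent=1))
    if write_trials:
        from .mocap_io import write_trial

        for trial, gt in study.iter_trials():
            d = outdir / "trials" / f"{trial.subject_id}_{trial.condition}"
            write_trial(trial, d)
            (d / "ground_truth.json").write_text(json.dumps(_gt_to_json(gt), indent=1))
    return study


def _gt_to_json(gt: synthcap.GroundTruth) -> dict:
    d = asdict(gt)
    d.pop("transition_mask")
    d.pop("generative")
    return json.loads(json.dumps(d, default=float))


def stage_extract(study: synthcap.StudyDataset, cfg: dict, outdir: Path) -> pd.DataFrame:
    table = features.extract_study_features(study, config=cfg["extraction"])
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "features.csv", index=False)
    return table


def stage_stats(table: pd.DataFrame, cfg: dict, outdir: Path) -> pd.DataFrame:
    s = cfg["stats"]
    screen = emostats.screen_all(
        table,
        n_perm=s["n_perm"],
        seed=cfg["seed"],
        alpha=s["alpha"],
        pairwise=s.get("pairwise", False),
        n_perm_pairwise=s.get("n_perm_pairwise", 1000),
        two_way=s.get("two_way", False),
    )
    outdir.mkdir(parents=True, exist_ok=True)
    screen.to_csv(outdir / "stats.csv")
    summary = {
        "alpha": s["alpha"],
        "n_features": int(len(screen)),
        "n_significant": screen.attrs["n_significant"],
    }
    if "n_interaction_significant" in screen.attrs:
        summary["n_interaction_significant"] = screen.attrs["n_interaction_significant"]
    (outdir / "stats_summary.json").write_text(json.dumps(summary, indent=1))
    return screen


def stage_classify(table: pd.DataFrame, cfg: dict, outdir: Path):
    reports, comparison = emoclassify.run_classification(
        table,
        config=cfg["classify"].get("models"),
        seed=cfg["seed"],
        test_fraction=cfg["classify"]["test_fraction"],
    )
    outdir.mkdir(parents=True, exist_ok=True)
    comparison.to_csv(outdir / "classification.csv")
    tree = reports.get("decision_tree")
    if tree is not None and tree.importances is not None:
        tree.importances.rename("gini_importance").to_csv(outdir / "tree_importances.csv")
    roc_rows = []
    for name, rep in reports.items():
        if rep.roc:
            for cls, r in rep.roc.items():
                for fpr, tpr in zip(r["fpr"], r["tpr"]):
                    roc_rows.append(
                        {"model": name, "class": cls, "fpr": fpr, "tpr": tpr}
                    )
    if roc_rows:
        pd.DataFrame(roc_rows).to_csv(outdir / "roc_points.csv", index=False)
    per_class = {
        name: rep.per_class.to_dict(orient="index") for name, rep in reports.items()
    }
    (outdir / "per_class_metrics.json").write_text(json.dumps(per_class, indent=1))
    return reports, comparison


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run all stages, writing artifacts and a JSON run manifest."""
    cfg = cfg or default_config()
    outdir = Path(outdir or cfg.get("output_dir", "results/pipeline"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config_hash(cfg),
        "versions": {
            "emogait": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "warnings": [],
    }
    collected: list[str] = []

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                out = fn(*args, **kwargs)
            collected.extend(f"{name}: {w.message}" for w in caught)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %s done in %.1fs", name, manifest["stages"][name]["seconds"])
        return out

    study = timed("simulate", stage_simulate, cfg, outdir)
    table = timed("extract", stage_extract, study, cfg, outdir)
    screen = timed("stats", stage_stats, table, cfg, outdir)
    _reports, comparison = timed("classify", stage_classify, table, cfg, outdir)
    manifest["warnings"] = collected[:200]
    manifest["summary"] = {
        "n_trials": int(len(table)),
        "n_significant_features": screen.attrs["n_significant"],
        "best_model": comparison["accuracy"].idxmax(),
        "best_accuracy": float(comparison["accuracy"].max()),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
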