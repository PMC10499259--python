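"""The 229-parameter feature catalog.

The catalog spans four categories — balance (COP), standing posture, gait
initiation and walking — and includes paired variants of the same core
quantity (cluster-relative vs. full COP statistics; normalized vs.
non-normalized lengths/times/speeds), so several names are modifications of
one underlying measure.

The registry is data: it ships as ``data/feature_registry.csv`` (editable
without touching code) and is reconciled at test time against the systematic
expansion below, which must enumerate exactly 229 names.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .gait_features import WALKING_PARAMS
from .standing_features import BALANCE_STATS, POSTURE_CHANNELS, VARIANTS

N_FEATURES = 229


def build_registry() -> pd.DataFrame:
    """Systematic expansion of the catalog: category x phase x side x
    statistic x variant."""
    rows: list[dict] = []

    def add(name, category, phase, side, variant, statistic, parameter, normalized):
        rows.append(
            dict(
                name=name,
                category=category,
                phase=phase,
                side=side,
                variant=variant,
                statistic=statistic,
                parameter=parameter,
                normalized=normalized,
            )
        )

    # --- balance: COP during standing --------------------------------------
    for variant in VARIANTS:
        for stat in BALANCE_STATS:
            stat_name, axis = stat.split(".")
            add(
                f"balance.standing.{variant}.{stat}",
                "balance", "standing", axis, variant, stat_name, "cop", False,
            )
    add(
        "balance.standing.clustered.n_loci.count",
        "balance", "standing", "none", "clustered", "count", "cop_loci", False,
    )

    # --- standing posture ---------------------------------------------------
    for ch in POSTURE_CHANNELS:
        for variant in VARIANTS:
            for stat in ("mean", "sd"):
                add(
                    f"posture.standing.{variant}.{stat}.{ch}",
                    "standing_posture", "standing", "none", variant, stat, ch, False,
                )
    for stat in ("mean", "sd"):
        add(
            f"posture.standing.full.{stat}.step_width_ankles",
            "standing_posture", "standing", "none", "full", stat,
            "step_width_ankles", False,
        )
        add(
            f"posture.standing.full.{stat}.base_of_support",
            "standing_posture", "standing", "none", "full", stat,
            "base_of_support", False,
        )
        add(
            f"posture.standing.clustered.{stat}.step_width_cop",
            "standing_posture", "standing", "none", "clustered", stat,
            "step_width_cop", False,
        )

    # --- gait initiation ----------------------------------------------------
    for step in ("step1", "step2"):
        for param in ("length", "duration", "speed", "height", "width"):
            for norm in (False, True):
                add(
                    f"gait_initiation.{step}.{'normalized' if norm else 'raw'}.{param}",
                    "gait_initiation", "initiation", step, "none", param, param, norm,
                )
    for param in ("swing_speed", "swing_width"):
        for norm in (False, True):
            add(
                f"gait_initiation.step1.{'normalized' if norm else 'raw'}.{param}",
                "gait_initiation", "initiation", "step1", "none", param, param, norm,
            )
    for norm in (False, True):
        add(
            f"gait_initiation.overall.{'normalized' if norm else 'raw'}.total_duration",
            "gait_initiation", "initiation", "overall", "none", "total_duration",
            "total_duration", norm,
        )

    # --- walking gait -------------------------------------------------------
    for side in ("left", "right"):
        for norm in (False, True):
            for stat in ("mean", "sd"):
                for param in WALKING_PARAMS:
                    add(
                        f"walking.{side}.{'normalized' if norm else 'raw'}.{stat}.{param}",
                        "walking", "walking", side, "none", stat, param, norm,
                    )
    for norm in (False, True):
        for stat in ("mean", "sd"):
            add(
                f"walking.overall.{'normalized' if norm else 'raw'}.{stat}.walking_speed",
                "walking", "walking", "overall", "none", stat, "walking_speed", norm,
            )

    # --- walking posture ----------------------------------------------------
    for ch in POSTURE_CHANNELS:
        for variant in VARIANTS:
            for stat in ("mean", "sd"):
                add(
                    f"walking_posture.{variant}.{stat}.{ch}",
                    "walking", "walking", "none", variant, stat, ch, False,
                )

    df = pd.DataFrame(rows)
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].tolist()
        raise RuntimeError(f"duplicate registry names: {dup}")
    if len(df) != N_FEATURES:
        raise RuntimeError(f"registry enumerates {len(df)} features, expected {N_FEATURES}")
    return df


def registry_path() -> Path:
    return Path(str(resources.files("emogait").joinpath("data/feature_registry.csv")))


def load_registry() -> pd.DataFrame:
    """The shipped registry CSV (falls back to the builder if absent)."""
    path = registry_path()
    if path.exists():
        return pd.read_csv(path)
    return build_registry()


def feature_names() -> list[str]:
    return load_registry()["name"].tolist()


def write_registry(path: str | Path | None = None) -> Path:
    path = Path(path) if path is not None else registry_path()
    build_registry().to_csv(path, index=False)
    return path


if __name__ == "__main__":
    print(f"wrote {write_registry()}")
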