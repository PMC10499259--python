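"""Marker and force-plate time-series containers and file formats.

Internal units are metres, seconds and newtons. Missing marker samples are
represented explicitly as NaN, never as silent zeros.

Two on-disk marker formats are supported: a plain-text TSV dialect (primary,
documented in the README) and the standard C3D container, the latter only when
the optional ``ezc3d`` package is importable. Force-plate records are CSV
tables with named columns ``Fx,Fy,Fz,Mx,My,Mz`` (and/or ``COPx,COPy``).

Coordinate frame: X = anterior(+)/posterior, Y = mediolateral, Z = vertical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

CONDITIONS = ("neutral", "happy", "relaxed", "sad", "fear")

FORCE_COLUMNS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")


@dataclass
class MarkerTrajectorySet:
    """Named 3-D marker trajectories sampled at a common rate.

    ``data`` maps marker name -> (n_frames, 3) float array in metres;
    missing samples are NaN.
    """

    rate: float
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("marker rate must be positive")
        lengths = {arr.shape[0] for arr in self.data.values()}
        if len(lengths) > 1:
            raise ValueError(f"markers differ in length: {sorted(lengths)}")
        for name, arr in self.data.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r} is not (n, 3)")

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[0] if self.data else 0

    @property
    def names(self) -> list[str]:
        return list(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def missing_mask(self, name: str) -> np.ndarray:
        """Per-frame boolean mask, True where any coordinate is missing."""
        return np.isnan(self.data[name]).any(axis=1)

    def window(self, t0: float, t1: float) -> "MarkerTrajectorySet":
        """Sub-trajectory covering [t0, t1) in seconds."""
        i0 = max(0, int(np.ceil(t0 * self.rate - 1e-9)))
        i1 = min(self.n_frames, int(np.floor(t1 * self.rate + 1e-9)))
        return MarkerTrajectorySet(
            self.rate, {k: v[i0:i1].copy() for k, v in self.data.items()}
        )

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(self.rate, {k: v.copy() for k, v in self.data.items()})


@dataclass
class ForcePlateRecord:
    """Force-plate channels about the plate origin.

    ``z0`` is the vertical offset of the plate origin below the contact
    surface (0 for a surface origin).  ``cop`` may carry a precomputed
    centre of pressure, in which case forces/moments are optional.
    """

    rate: float
    forces: np.ndarray | None = None   # (n, 3) N
    moments: np.ndarray | None = None  # (n, 3) N*m
    cop: np.ndarray | None = None      # (n, 2) m
    z0: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("force-plate rate must be positive")
        lengths = {
            arr.shape[0]
            for arr in (self.forces, self.moments, self.cop)
            if arr is not None
        }
        if len(lengths) > 1:
            raise ValueError("force-plate channels differ in length")
        if not lengths:
            raise ValueError("force-plate record has no channels")

    @property
    def n_samples(self) -> int:
        for arr in (self.forces, self.moments, self.cop):
            if arr is not None:
                return arr.shape[0]
        return 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass
class COPSeries:
    """Centre-of-pressure positions (AP, ML) with per-sample validity."""

    rate: float
    xy: np.ndarray          # (n, 2) m, columns (x_ap, y_ml)
    valid: np.ndarray       # (n,) bool

    @property
    def n_samples(self) -> int:
        return self.xy.shape[0]


@dataclass
class TrialRecording:
    """One subject x condition session: markers + force plate + metadata."""

    subject_id: str
    gender: str
    condition: str
    markers: MarkerTrajectorySet
    forceplate: ForcePlateRecord
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )


# ---------------------------------------------------------------------------
# TSV marker dialect
#
#   line 1:  rate<TAB><hz>
#   line 2:  <name>_X<TAB><name>_Y<TAB><name>_Z ...  (one triplet per marker)
#   line 3+: one row per frame; blank cells are missing samples
# ---------------------------------------------------------------------------

def write_markers_tsv(m: MarkerTrajectorySet, path: str | Path) -> None:
    """Write the TSV dialect.  Values use shortest round-trip float repr, so a
    read-back is bit-exact."""
    path = Path(path)
    names = m.names
    header = "\t".join(f"{n}_{ax}" for n in names for ax in "XYZ")
    stacked = np.hstack([m.data[n] for n in names]) if names else np.empty((0, 0))
    with path.open("w") as fh:
        fh.write(f"rate\t{m.rate!r}\n")
        fh.write(header + "\n")
        for row in stacked:
            fh.write("\t".join("" if np.isnan(v) else repr(float(v)) for v in row) + "\n")


def read_markers_tsv(path: str | Path) -> MarkerTrajectorySet:
    path = Path(path)
    with path.open() as fh:
        meta = fh.readline().rstrip("\n").split("\t")
        if len(meta) != 2 or meta[0] != "rate":
            raise ValueError(f"{path}: malformed metadata line {meta!r}")
        rate = float(meta[1])
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) % 3 != 0 or not header[0]:
            raise ValueError(f"{path}: malformed header (column count {len(header)})")
        names = []
        for i in range(0, len(header), 3):
            base = header[i]
            if not base.endswith("_X"):
                raise ValueError(f"{path}: header column {header[i]!r} not <name>_X")
            names.append(base[:-2])
        rows = []
        for lineno, line in enumerate(fh, start=3):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            rows.append([np.nan if c == "" else float(c) for c in cells])
    arr = np.asarray(rows, dtype=float).reshape(len(rows), len(names), 3)
    data = {n: arr[:, i, :].copy() for i, n in enumerate(names)}
    return MarkerTrajectorySet(rate, data)


def read_markers(path: str | Path, dialect: str = "tsv") -> MarkerTrajectorySet:
    """Read marker trajectories (``dialect`` in {"tsv", "c3d"})."""
    if dialect == "tsv":
        return read_markers_tsv(path)
    if dialect == "c3d":
        return read_markers_c3d(path)
    raise ValueError(f"unknown marker dialect {dialect!r}")


def write_markers(m: MarkerTrajectorySet, path: str | Path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        write_markers_tsv(m, path)
    else:
        raise ValueError(f"unsupported write dialect {dialect!r}")


def read_markers_c3d(path: str | Path) -> MarkerTrajectorySet:
    """Read a C3D file via the optional ``ezc3d`` package (mm converted to m)."""
    try:
        import ezc3d  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D requires the optional 'ezc3d' package; "
            "use the TSV dialect otherwise"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    data = {}
    for i, name in enumerate(labels):
        xyz = pts[:3, i, :].T.astype(float) / 1000.0
        data[name] = xyz
    return MarkerTrajectorySet(rate, data)


# ---------------------------------------------------------------------------
# Force-plate CSV
# ---------------------------------------------------------------------------

def write_forceplate_csv(fp: ForcePlateRecord, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {}
    if fp.forces is not None:
        cols.update(zip(("Fx", "Fy", "Fz"), fp.forces.T))
    if fp.moments is not None:
        cols.update(zip(("Mx", "My", "Mz"), fp.moments.T))
    if fp.cop is not None:
        cols.update(zip(("COPx", "COPy"), fp.cop.T))
    df = pd.DataFrame(cols)
    with Path(path).open("w") as fh:
        fh.write(f"# rate_hz={fp.rate!r} z0={fp.z0!r}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_forceplate_csv(path: str | Path) -> ForcePlateRecord:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing metadata comment line")
        meta = dict(kv.split("=") for kv in first[1:].split())
        df = pd.read_csv(fh)
    forces = moments = cop = None
    if {"Fx", "Fy", "Fz"} <= set(df.columns):
        forces = df[["Fx", "Fy", "Fz"]].to_numpy(float)
    if {"Mx", "My", "Mz"} <= set(df.columns):
        moments = df[["Mx", "My", "Mz"]].to_numpy(float)
    if {"COPx", "COPy"} <= set(df.columns):
        cop = df[["COPx", "COPy"]].to_numpy(float)
    return ForcePlateRecord(
        rate=float(meta["rate_hz"]),
        forces=forces,
        moments=moments,
        cop=cop,
        z0=float(meta.get("z0", 0.0)),
    )


# ---------------------------------------------------------------------------
# COP mechanics and rate synchronization
# ---------------------------------------------------------------------------

def cop_from_forceplate(fp: ForcePlateRecord, contact_threshold: float = 20.0) -> COPSeries:
    """Centre of pressure from plate forces and moments.

    COPx = (-My - Fx*z0) / Fz ;  COPy = (Mx - Fy*z0) / Fz.
    Samples with Fz below ``contact_threshold`` (N) are flagged invalid.
    A precomputed COP channel, when present, is passed through (validity still
    gated on Fz where forces are available).
    """
    if fp.cop is not None:
        valid = np.ones(fp.n_samples, dtype=bool)
        if fp.forces is not None:
            valid = fp.forces[:, 2] >= contact_threshold
        return COPSeries(fp.rate, fp.cop.astype(float).copy(), valid)
    if fp.forces is None or fp.moments is None:
        raise ValueError("record carries neither COP nor forces+moments")
    fx, fy, fz = fp.forces.T
    mx, my, _ = fp.moments.T
    valid = fz >= contact_threshold
    if not valid.any():
        raise ValueError("all samples below the contact threshold")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (-my - fx * fp.z0) / fz
        y = (mx - fy * fp.z0) / fz
    xy = np.column_stack([x, y])
    xy[~valid] = np.nan
    return COPSeries(fp.rate, xy, valid)


def _resample(arr: np.ndarray, up: int, down: int, n_out: int) -> np.ndarray:
    out = resample_poly(arr, up, down, axis=0, padtype="line")
    return out[:n_out]


def synchronize(fp: ForcePlateRecord, target_rate: float) -> ForcePlateRecord:
    """Anti-alias filter and resample a force-plate record to ``target_rate``.

    ``target_rate`` must not exceed the record's rate (the study configuration
    is 1000 Hz force down to 120 Hz marker frames).
    """
    if target_rate > fp.rate:
        raise ValueError(f"target rate {target_rate} above record rate {fp.rate}")
    if target_rate == fp.rate:
        return replace(fp)
    frac = Fraction(target_rate / fp.rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    n_out = int(np.floor((fp.n_samples - 1) * target_rate / fp.rate)) + 1
    kwargs = {}
    for name in ("forces", "moments", "cop"):
        arr = getattr(fp, name)
        kwargs[name] = _resample(arr, up, down, n_out) if arr is not None else None
    return ForcePlateRecord(rate=target_rate, z0=fp.z0, **kwargs)


# ---------------------------------------------------------------------------
# Trial directories (markers.tsv + forceplate.csv + meta.json)
# ---------------------------------------------------------------------------

def write_trial(trial: TrialRecording, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_markers_tsv(trial.markers, directory / "markers.tsv")
    write_forceplate_csv(trial.forceplate, directory / "forceplate.csv")
    meta = {
        "subject_id": trial.subject_id,
        "gender": trial.gender,
        "condition": trial.condition,
        "annotations": trial.annotations,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return directory


def read_trial(directory: str | Path) -> TrialRecording:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    return TrialRecording(
        subject_id=meta["subject_id"],
        gender=meta["gender"],
        condition=meta["condition"],
        markers=read_markers_tsv(directory / "markers.tsv"),
        forceplate=read_forceplate_csv(directory / "forceplate.csv"),
        annotations=meta.get("annotations", {}),
    )
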