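"""Readers and writers for every external artifact of the pipeline.

Supported formats (all plain CSV):

* pose tracks — either the three-row-header table emitted by common
  marker-less pose estimators (scorer / bodyparts / coords) or a plain
  long table with columns ``frame, body_point, u, v, likelihood``;
* DLT coefficients — 11 rows × one column per camera (easyWand column
  convention, coefficient order L1..L11);
* oxygen traces — columns ``time, o2[, temp]``; the time unit is taken
  from the header (``time_s`` / ``time_min`` / ``time_h``) or passed
  explicitly, and canonicalized to hours;
* cycle schedules and fish metadata — one row per cycle / individual.

Readers never silently drop rows: densified or rejected counts are
available through ``return_report=True`` where applicable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import CameraModel, CycleSchedule, FishMeta, OxygenTrace, PointTrack, PoseTrackSet

LONG_COLUMNS = ["frame", "body_point", "u", "v", "likelihood"]


# ---------------------------------------------------------------------------
# pose tracks
# ---------------------------------------------------------------------------

def _densify(frames: np.ndarray, cols: dict[str, np.ndarray]) -> tuple[np.ndarray, dict, int]:
    """Fill absent frame numbers with NaN coordinates and likelihood 0."""
    if len(frames) == 0:
        raise FormatError("pose table holds no rows")
    if np.any(np.diff(frames) <= 0):
        raise ValidationError("pose table frames must be strictly increasing")
    lo, hi = int(frames[0]), int(frames[-1])
    full = np.arange(lo, hi + 1)
    n_missing = len(full) - len(frames)
    if n_missing == 0:
        return full, cols, 0
    idx = (frames - lo).astype(int)
    dense = {}
    for name, arr in cols.items():
        out = np.full(len(full), np.nan if name != "likelihood" else 0.0)
        out[idx] = arr
        dense[name] = out
    return full, dense, n_missing


def read_pose_tracks(
    path: str | Path,
    dialect: str = "auto",
    camera_id: str | None = None,
    fps: float = 90.0,
    return_report: bool = False,
):
    """Read one camera's pose-track table.

    Parameters
    ----------
    dialect
        ``"dlc"`` (three-row header), ``"long"`` or ``"auto"`` (sniff).
    camera_id
        Label for the camera; defaults to the file stem.
    return_report
        Also return a dict with row/densification counts.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"pose file not found: {path}")
    if camera_id is None:
        camera_id = path.stem
    if dialect == "auto":
        with open(path) as fh:
            first = fh.readline()
        dialect = "dlc" if first.lower().startswith("scorer") else "long"

    if dialect == "dlc":
        frames, points, report = _read_dlc(path)
    elif dialect == "long":
        frames, points, report = _read_long(path)
    else:
        raise FormatError(f"unknown pose dialect: {dialect!r}")

    pts = {name: PointTrack(u=c["u"], v=c["v"], likelihood=c["likelihood"]) for name, c in points.items()}
    pose = PoseTrackSet(camera_id=camera_id, frames=frames, points=pts, fps=fps)
    if return_report:
        return pose, report
    return pose


def _read_dlc(path: Path):
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    coords_seen = {c[2] for c in df.columns}
    for needed in ("x", "y", "likelihood"):
        if needed not in coords_seen:
            raise FormatError(f"pose table missing coords column {needed!r}")
    frames = df.index.to_numpy()
    bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
    raw: dict[str, dict[str, np.ndarray]] = {}
    for bp in bodyparts:
        sub = {}
        for coord, key in (("x", "u"), ("y", "v"), ("likelihood", "likelihood")):
            col = [c for c in df.columns if c[1] == bp and c[2] == coord]
            if not col:
                raise FormatError(f"pose table missing column {bp}/{coord}")
            sub[key] = df[col[0]].to_numpy(dtype=float)
        raw[bp] = sub
    # densify on a shared frame axis
    out: dict[str, dict[str, np.ndarray]] = {}
    n_missing = 0
    for bp, cols in raw.items():
        full, dense, n_missing = _densify(np.asarray(frames), cols)
        out[bp] = dense
    report = {"rows_read": len(frames), "frames_densified": n_missing}
    return full, out, report


def _read_long(path: Path):
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pose table missing column {missing[0]!r}")
    out: dict[str, dict[str, np.ndarray]] = {}
    n_missing = 0
    full = None
    for bp, sub in df.groupby("body_point", sort=False):
        frames = sub["frame"].to_numpy()
        cols = {k: sub[k].to_numpy(dtype=float) for k in ("u", "v", "likelihood")}
        full, dense, n_missing = _densify(frames, cols)
        out[str(bp)] = dense
    if full is None:
        raise FormatError("pose table holds no rows")
    report = {"rows_read": int(len(df)), "frames_densified": n_missing}
    return full, out, report


def write_pose_tracks(pose: PoseTrackSet, path: str | Path, dialect: str = "dlc") -> None:
    """Write a pose-track table in either dialect (inverse of the reader)."""
    path = Path(path)
    if dialect == "dlc":
        cols = {}
        for bp, pt in pose.points.items():
            cols[("videba", bp, "x")] = pt.u
            cols[("videba", bp, "y")] = pt.v
            cols[("videba", bp, "likelihood")] = pt.likelihood
        df = pd.DataFrame(cols, index=pose.frames)
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scorer", "bodyparts", "coords"])
        df.index.name = None
        df.to_csv(path)
    elif dialect == "long":
        parts = []
        for bp, pt in pose.points.items():
            parts.append(
                pd.DataFrame(
                    {
                        "frame": pose.frames,
                        "body_point": bp,
                        "u": pt.u,
                        "v": pt.v,
                        "likelihood": pt.likelihood,
                    }
                )
            )
        pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown pose dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# DLT coefficients
# ---------------------------------------------------------------------------

def read_dlt_coefficients(path: str | Path) -> list[CameraModel]:
    """Read an 11-row × n-camera DLT coefficient table (easyWand convention).

    A single header row of camera labels is accepted; coefficient order is
    L1..L11 down the rows.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"DLT coefficient file not found: {path}")
    probe = pd.read_csv(path, header=None, nrows=1)
    has_header = not np.issubdtype(probe.dtypes.iloc[0], np.number)
    df = pd.read_csv(path, header=0 if has_header else None, float_precision="round_trip")
    if df.shape[0] != 11:
        raise FormatError(
            f"DLT coefficient file must have exactly 11 rows per camera, got {df.shape[0]}"
        )
    cams = []
    for j, col in enumerate(df.columns):
        label = str(col) if has_header else f"cam{j}"
        cams.append(CameraModel(L=df[col].to_numpy(dtype=float), camera_id=label))
    return cams


def write_dlt_coefficients(cameras: list[CameraModel], path: str | Path) -> None:
    df = pd.DataFrame({c.camera_id or f"cam{j}": c.L for j, c in enumerate(cameras)})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# oxygen traces, schedules, metadata
# ---------------------------------------------------------------------------

_TIME_FACTORS = {"s": 1.0 / 3600.0, "min": 1.0 / 60.0, "h": 1.0}


def read_oxygen_trace(path: str | Path, time_unit: str | None = None) -> OxygenTrace:
    """Read a dissolved-oxygen log; time is canonicalized to hours.

    The time unit comes from the header (``time_s``, ``time_min``,
    ``time_h`` or bare ``time`` = hours) unless ``time_unit`` overrides it.
    """
    df = pd.read_csv(path)
    time_col = next((c for c in df.columns if c.split("_")[0].lower() == "time"), None)
    if time_col is None:
        raise FormatError("oxygen trace must have a time column")
    if "o2" not in df.columns:
        raise FormatError("oxygen trace must have an o2 column")
    if time_unit is None:
        suffix = time_col.partition("_")[2].lower()
        time_unit = suffix if suffix in _TIME_FACTORS else "h"
    if time_unit not in _TIME_FACTORS:
        raise FormatError(f"unknown time unit {time_unit!r}")
    t = df[time_col].to_numpy(dtype=float) * _TIME_FACTORS[time_unit]
    temp = df["temp"].to_numpy(dtype=float) if "temp" in df.columns else None
    return OxygenTrace(t=t, o2=df["o2"].to_numpy(dtype=float), temp=temp)


def write_oxygen_trace(trace: OxygenTrace, path: str | Path) -> None:
    cols = {"time_h": trace.t, "o2": trace.o2}
    if trace.temp is not None:
        cols["temp"] = trace.temp
    pd.DataFrame(cols).to_csv(path, index=False)


def read_cycle_schedule(path: str | Path) -> list[CycleSchedule]:
    """Read a measurement-cycle schedule.

    Columns: ``cycle_id, U[, replicate, condition, flush_min, equil_min,
    measure_min, start_h]``.  When ``start_h`` is absent, cycles are
    assumed back-to-back from t = 0.
    """
    df = pd.read_csv(path)
    for c in ("cycle_id", "U"):
        if c not in df.columns:
            raise FormatError(f"cycle schedule missing column {c!r}")
    cycles = []
    t0 = 0.0
    for _, row in df.iterrows():
        cyc = CycleSchedule(
            cycle_id=str(row["cycle_id"]),
            U=float(row["U"]),
            replicate=int(row.get("replicate", 1)),
            condition=str(row.get("condition", "steady")),
            flush_min=float(row.get("flush_min", 5.0)),
            equil_min=float(row.get("equil_min", 2.0)),
            measure_min=float(row.get("measure_min", 20.0)),
            start_h=float(row["start_h"]) if "start_h" in df.columns else t0,
        )
        t0 = cyc.start_h + cyc.duration_h
        cycles.append(cyc)
    return cycles


def write_cycle_schedule(cycles: list[CycleSchedule], path: str | Path) -> None:
    pd.DataFrame(
        {
            "cycle_id": [c.cycle_id for c in cycles],
            "U": [c.U for c in cycles],
            "replicate": [c.replicate for c in cycles],
            "condition": [c.condition for c in cycles],
            "flush_min": [c.flush_min for c in cycles],
            "equil_min": [c.equil_min for c in cycles],
            "measure_min": [c.measure_min for c in cycles],
            "start_h": [c.start_h for c in cycles],
        }
    ).to_csv(path, index=False)


def read_fish_table(path: str | Path) -> list[FishMeta]:
    """Read fish metadata; masses in kg (``mass_kg``) or grams (``mass_g``)."""
    df = pd.read_csv(path)
    if "individual_id" not in df.columns:
        raise FormatError("fish table missing column 'individual_id'")
    if "mass_kg" in df.columns:
        mass = df["mass_kg"].to_numpy(dtype=float)
    elif "mass_g" in df.columns:
        mass = df["mass_g"].to_numpy(dtype=float) / 1000.0
    else:
        raise FormatError("fish table missing column 'mass_kg' (or 'mass_g')")
    return [
        FishMeta(individual_id=str(i), mass_kg=float(m))
        for i, m in zip(df["individual_id"], mass)
    ]


def read_fish_meta(path: str | Path) -> FishMeta:
    """Read a single-individual metadata file."""
    fish = read_fish_table(path)
    if len(fish) != 1:
        raise FormatError(f"expected exactly one fish in {path}, got {len(fish)}")
    return fish[0]


def write_fish_table(fish: list[FishMeta], path: str | Path) -> None:
    pd.DataFrame(
        {"individual_id": [f.individual_id for f in fish], "mass_kg": [f.mass_kg for f in fish]}
    ).to_csv(path, index=False)
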