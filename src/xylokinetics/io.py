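"""Readers and writers for the pipeline's tabular formats.

All tables travel as UTF-8 CSV with a header row.  Each reader validates its
type invariants and raises a categorised error (:mod:`xylokinetics.errors`)
on violation; unknown extra columns are preserved but ignored.  Column names
can be remapped (e.g. for QuPath export dialects) via ``column_map``; a
default map covering both the canonical headers and QuPath's English export
headers is applied first.

Units: stem diameter is millimetres and height centimetres at the I/O
boundary; all cell-level lengths are micrometres.  A cell table exported in
pixels can be converted by passing ``pixel_size`` (micrometres per pixel).
Water potentials are megapascals and must be non-positive.  Days are
integers from the experiment start.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContiguityError, RowError, SchemaError

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_detection_table",
    "write_detection_table",
    "read_growth_table",
    "write_growth_table",
    "read_lwp_table",
    "write_lwp_table",
    "read_environment_log",
    "write_environment_log",
    "read_schedule_table",
    "write_schedule_table",
    "read_truth",
    "write_truth",
]

# QuPath's detection export repurposes "Nucleus: Area" for the cell lumen in
# wood sections; the map keeps that assignment overridable.
DEFAULT_COLUMN_MAP = {
    "Image": "sample_id",
    "Class": "cell_class",
    "Cell: Area": "cell_area",
    "Nucleus: Area": "lumen_area",
    "Centroid X µm": "centroid_x",
    "Centroid Y µm": "centroid_y",
    "Centroid X": "centroid_x",
    "Centroid Y": "centroid_y",
}

DETECTION_COLUMNS = [
    "sample_id",
    "cell_class",
    "cell_area",
    "lumen_area",
    "centroid_x",
    "centroid_y",
]
GROWTH_COLUMNS = ["tree_id", "block", "treatment", "day", "diameter", "height"]
LWP_COLUMNS = ["tree_id", "day", "psi_pd"]
ENVIRONMENT_COLUMNS = ["timestamp", "temperature", "relative_humidity"]
SCHEDULE_COLUMNS = ["label", "start_day", "end_day", "status"]

_CLASS_ALIASES = {
    "fibre": "fibre",
    "fiber": "fibre",
    "fibres": "fibre",
    "vessel": "vessel",
    "vessels": "vessel",
}


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column '{col}'", column=col)


def _numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna() & df[col].notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(f"{what}: non-numeric value in '{col}' at row {idx}", row=idx)
    if s.isna().any():
        idx = int(np.flatnonzero(s.isna().to_numpy())[0])
        raise RowError(f"{what}: missing value in '{col}' at row {idx}", row=idx)
    return s


def read_detection_table(
    path,
    column_map: dict | None = None,
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Read a cell-detection export into the canonical cell-record table.

    Rows whose class is neither fibre nor vessel (any spelling/case) are kept
    with class ``other``.  If ``pixel_size`` (um/px) is given, centroid
    coordinates are scaled by it and areas by its square.
    """
    df = pd.read_csv(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = df.rename(columns={k: v for k, v in cmap.items() if k in df.columns})
    _require(df, DETECTION_COLUMNS, "detection table")

    out = df.copy()
    out["cell_class"] = (
        out["cell_class"].astype(str).str.strip().str.lower().map(_CLASS_ALIASES)
        .fillna("other")
    )
    for col in ("cell_area", "lumen_area", "centroid_x", "centroid_y"):
        out[col] = _numeric(out, col, "detection table").astype(float)
    if pixel_size is not None:
        if pixel_size <= 0:
            raise RowError("pixel_size must be > 0")
        out[["centroid_x", "centroid_y"]] *= pixel_size
        out[["cell_area", "lumen_area"]] *= pixel_size**2

    bad = out["cell_area"] <= 0
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(f"detection table: cell_area <= 0 at row {idx}", row=idx)
    bad = (out["lumen_area"] < 0) | (out["lumen_area"] >= out["cell_area"])
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(
            f"detection table: lumen_area outside [0, cell_area) at row {idx}",
            row=idx,
        )
    coords = out[["centroid_x", "centroid_y"]].to_numpy()
    if not np.all(np.isfinite(coords)):
        idx = int(np.flatnonzero(~np.isfinite(coords).all(axis=1))[0])
        raise RowError(f"detection table: non-finite centroid at row {idx}", row=idx)
    return out


def write_detection_table(df: pd.DataFrame, path) -> None:
    _require(df, DETECTION_COLUMNS, "detection table")
    df.to_csv(path, index=False)


def read_growth_table(path) -> pd.DataFrame:
    """Read daily per-tree diameter/height series; days must be contiguous."""
    df = pd.read_csv(path)
    _require(df, GROWTH_COLUMNS, "growth table")
    out = df.copy()
    out["day"] = _numeric(out, "day", "growth table").astype(int)
    for col in ("diameter", "height"):
        out[col] = _numeric(out, col, "growth table").astype(float)
    if (out["diameter"] <= 0).any():
        idx = int(np.flatnonzero((out["diameter"] <= 0).to_numpy())[0])
        raise RowError(f"growth table: diameter <= 0 at row {idx}", row=idx)
    for tid, grp in out.groupby("tree_id", sort=False):
        days = np.sort(grp["day"].to_numpy())
        if len(days) != len(np.unique(days)):
            raise ContiguityError(f"growth table: duplicate day for tree {tid}")
        gaps = np.flatnonzero(np.diff(days) != 1)
        if gaps.size:
            missing = int(days[gaps[0]] + 1)
            raise ContiguityError(
                f"growth table: tree {tid} is missing day {missing}"
            )
    return out


def write_growth_table(df: pd.DataFrame, path) -> None:
    _require(df, GROWTH_COLUMNS, "growth table")
    df.to_csv(path, index=False)


def read_lwp_table(path) -> pd.DataFrame:
    """Read pre-dawn leaf water potential records (MPa, <= 0)."""
    df = pd.read_csv(path)
    _require(df, LWP_COLUMNS, "LWP table")
    out = df.copy()
    out["day"] = _numeric(out, "day", "LWP table").astype(int)
    out["psi_pd"] = _numeric(out, "psi_pd", "LWP table").astype(float)
    bad = out["psi_pd"] > 0
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(
            f"LWP table: positive water potential at row {idx} "
            "(psi_pd is stored as negative MPa)",
            row=idx,
        )
    return out


def write_lwp_table(df: pd.DataFrame, path) -> None:
    _require(df, LWP_COLUMNS, "LWP table")
    df.to_csv(path, index=False)


def read_environment_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _require(df, ENVIRONMENT_COLUMNS, "environment log")
    out = df.copy()
    for col in ("temperature", "relative_humidity"):
        out[col] = _numeric(out, col, "environment log").astype(float)
    bad = (out["relative_humidity"] < 0) | (out["relative_humidity"] > 100)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(f"environment log: RH outside [0, 100] at row {idx}", row=idx)
    return out


def write_environment_log(df: pd.DataFrame, path) -> None:
    _require(df, ENVIRONMENT_COLUMNS, "environment log")
    df.to_csv(path, index=False)


def read_schedule_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SCHEDULE_COLUMNS, "schedule table")
    out = df.copy()
    out["start_day"] = _numeric(out, "start_day", "schedule").astype(int)
    out["end_day"] = _numeric(out, "end_day", "schedule").astype(int)
    bad = ~out["status"].isin(["droughted", "watered"])
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(f"schedule: unknown status at row {idx}", row=idx)
    return out


def write_schedule_table(df: pd.DataFrame, path) -> None:
    _require(df, SCHEDULE_COLUMNS, "schedule table")
    df.to_csv(path, index=False)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth(truth: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=2, default=_default))
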