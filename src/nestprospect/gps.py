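"""Reading, validation, and cleaning of GPS fix tables.

A fix table is delimited text with one row per GPS fix:
``female_id, timestamp, x, y, dop`` (projected coordinates in meters) or
``female_id, timestamp, lon, lat, dop`` (geographic coordinates in degrees).
Timestamps are ISO-8601 local standard time; no timezone conversion is
performed anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

_REQUIRED_COLS = {
    "projected": ["female_id", "timestamp", "x", "y", "dop"],
    "geographic": ["female_id", "timestamp", "lon", "lat", "dop"],
}


class SchemaError(ValueError):
    """The fix table is missing required columns."""


class DataError(ValueError):
    """A value in the fix table violates a domain constraint."""


@dataclass
class Trajectory:
    """Time-ordered GPS fixes for one female.

    ``fixes`` columns: timestamp (datetime64), x, y (meters, or degrees
    lon/lat when ``mode == "geographic"``), dop.
    """

    female_id: str
    fixes: pd.DataFrame
    mode: str = "projected"

    def __post_init__(self) -> None:
        if self.mode not in ("projected", "geographic"):
            raise ValueError(f"unknown coordinate mode {self.mode!r}")
        self.fixes = self.fixes.sort_values("timestamp", kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(float)


@dataclass
class ReadReport:
    """Row-level problems encountered while parsing a fix table."""

    n_rows: int = 0
    n_kept: int = 0
    bad_rows: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)
    n_duplicates: int = 0


def read_fixes(path, coordinate_mode: str = "projected") -> tuple[list[Trajectory], ReadReport]:
    """Read a delimited fix table into one :class:`Trajectory` per female.

    Rows are sorted by timestamp within each female.  Malformed rows
    (unparseable timestamp or coordinates) are collected into the report
    with their 1-based line numbers rather than aborting the read.
    Duplicate ``(female_id, timestamp)`` rows keep the first occurrence.
    """
    cols = _REQUIRED_COLS[coordinate_mode]
    df = pd.read_csv(path, dtype={"female_id": str})
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"fix table missing required columns: {missing}")

    report = ReadReport(n_rows=len(df))
    if df.empty:
        logger.warning("fix table %s has a header but no rows", path)
        return [], report

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    xcol, ycol = cols[2], cols[3]
    num = df[[xcol, ycol, "dop"]].apply(pd.to_numeric, errors="coerce")
    bad = ts.isna() | num.isna().any(axis=1)
    for idx in df.index[bad]:
        reason = "unparseable timestamp" if pd.isna(ts[idx]) else "non-numeric coordinate or dop"
        report.bad_rows.append((int(idx) + 2, reason))  # +2: header line + 1-based
    df = df.loc[~bad].assign(timestamp=ts[~bad], **{c: num.loc[~bad, c] for c in num})

    if (df["dop"] < 0).any():
        raise DataError("negative DOP values present")

    dup = df.duplicated(subset=["female_id", "timestamp"], keep="first")
    report.n_duplicates = int(dup.sum())
    df = df.loc[~dup]
    report.n_kept = len(df)

    out = []
    for fid, grp in df.groupby("female_id", sort=True):
        g = grp.rename(columns={xcol: "x", ycol: "y"})[["timestamp", "x", "y", "dop"]]
        out.append(Trajectory(str(fid), g.reset_index(drop=True), mode=coordinate_mode))
    return out, report


def write_fixes(trajectories, path) -> None:
    """Write trajectories back to a single delimited fix table."""
    frames = []
    for tr in trajectories:
        g = tr.fixes.copy()
        g.insert(0, "female_id", tr.female_id)
        if tr.mode == "geographic":
            g = g.rename(columns={"x": "lon", "y": "lat"})
        frames.append(g)
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format="%.6f")


def filter_dop(trajectory: Trajectory, threshold: float = 7.0) -> Trajectory:
    """Drop fixes whose dilution of precision exceeds ``threshold``.

    The rule is strict: a fix with ``dop == threshold`` is retained,
    matching removal of fixes with DOP strictly greater than 7.
    """
    dop = trajectory.fixes["dop"]
    if (dop < 0).any():
        raise DataError(f"negative DOP in trajectory {trajectory.female_id}")
    kept = trajectory.fixes.loc[dop <= threshold].reset_index(drop=True)
    return Trajectory(trajectory.female_id, kept, mode=trajectory.mode)


def _haversine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    lon1, lat1, lon2, lat2 = map(np.radians, (a[..., 0], a[..., 1], b[..., 0], b[..., 1]))
    h = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def point_distance(a, b, mode: str = "projected") -> float:
    """Distance in meters between two points in the same coordinate mode.

    Projected mode is planar Euclidean; geographic mode is great-circle
    (haversine) on a 6,371,000-m sphere, ample precision at sub-kilometer
    scales.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if mode == "projected":
        return float(np.hypot(*(a - b)))
    if mode == "geographic":
        return float(_haversine(a, b))
    raise ValueError(f"unknown coordinate mode {mode!r}")


def pairwise_distances(points: np.ndarray, mode: str = "projected") -> np.ndarray:
    """Full symmetric distance matrix in meters."""
    pts = np.asarray(points, float)
    if mode == "projected":
        d = pts[:, None, :] - pts[None, :, :]
        return np.hypot(d[..., 0], d[..., 1])
    if mode == "geographic":
        return _haversine(pts[:, None, :], pts[None, :, :])
    raise ValueError(f"unknown coordinate mode {mode!r}")


def distances_to_point(points: np.ndarray, ref, mode: str = "projected") -> np.ndarray:
    """Distance in meters from each row of ``points`` to a single reference point."""
    pts = np.atleast_2d(np.asarray(points, float))
    ref = np.asarray(ref, float)
    if mode == "projected":
        return np.hypot(pts[:, 0] - ref[0], pts[:, 1] - ref[1])
    if mode == "geographic":
        return _haversine(pts, ref[None, :])
    raise ValueError(f"unknown coordinate mode {mode!r}")
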