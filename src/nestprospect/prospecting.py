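"""Clustered laying patches (CLPs), recess classification, and recursion counts.

The core construction: laying-period GPS fixes are merged into clustered
laying patches by single-linkage agglomeration with a 150-m inter-point
threshold (two fixes belong to the same patch when connected by a chain of
pairwise distances within the threshold).  During incubation, any fix more
than 27.5 m from the nest is a recess movement; a recess "revisits" a CLP
when it falls within a 45-m radius buffer of that patch's centroid.  The
per-attempt summary — proportion of recesses to CLPs and number of distinct
CLPs visited — feeds the nest-fate model.

All spatial rules use inclusive (<=) boundaries at the 150-m linkage and
45-m buffer radii; the recess rule is strictly greater-than 27.5 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .gps import distances_to_point, pairwise_distances

RECESS_THRESHOLD_M = 27.5
LINKAGE_RADIUS_M = 150.0
BUFFER_RADIUS_M = 45.0


@dataclass
class CLP:
    """A clustered laying patch: one merged cluster of laying-period fixes."""

    clp_id: int
    centroid_xy: tuple[float, float]
    member_index: list[int]
    visit_count: int = 0

    @property
    def n_members(self) -> int:
        return len(self.member_index)


@dataclass
class ProspectingSummary:
    attempt_id: str
    total_recesses: int
    recesses_to_clp: int
    n_clp_total: int
    n_clp_visited: int
    proportion_to_clp: float = field(init=False)

    def __post_init__(self) -> None:
        if self.recesses_to_clp > self.total_recesses:
            raise ValueError("recesses_to_clp exceeds total_recesses")
        self.proportion_to_clp = (
            self.recesses_to_clp / self.total_recesses if self.total_recesses else 0.0
        )


def classify_recesses(incubation_fixes: pd.DataFrame, nest_xy,
                      threshold_m: float = RECESS_THRESHOLD_M,
                      mode: str = "projected") -> pd.DataFrame:
    """Label each incubation fix as on-nest or recess by distance to the nest.

    Strict inequality: a fix at exactly ``threshold_m`` is on-nest.  Returns
    a copy with ``distance_to_nest`` (meters, kept for the resource-selection
    distance-to-nest covariate) and ``is_recess`` columns.
    """
    if nest_xy is None:
        raise ValueError("classify_recesses requires a nest location")
    out = incubation_fixes.copy()
    if out.empty:
        out["distance_to_nest"] = np.array([], float)
        out["is_recess"] = np.array([], bool)
        return out
    d = distances_to_point(out[["x", "y"]].to_numpy(float), np.asarray(nest_xy, float), mode)
    out["distance_to_nest"] = d
    out["is_recess"] = d > threshold_m
    return out


def _mean_point(points: np.ndarray, mode: str) -> np.ndarray:
    if mode == "projected":
        return points.mean(axis=0)
    # geographic: average on the unit sphere, then back to lon/lat
    lon, lat = np.radians(points[:, 0]), np.radians(points[:, 1])
    v = np.stack([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=1).mean(axis=0)
    v /= np.linalg.norm(v)
    return np.degrees([np.arctan2(v[1], v[0]), np.arcsin(v[2])])


def cluster_laying_locations(laying_fixes: pd.DataFrame,
                             linkage_radius_m: float = LINKAGE_RADIUS_M,
                             mode: str = "projected") -> list[CLP]:
    """Single-linkage clustering of laying-period fixes into CLPs.

    Two fixes share a patch iff connected by a chain of pairwise distances
    <= ``linkage_radius_m``.  Centroid is the arithmetic mean of member
    coordinates (unit-sphere mean in geographic mode).  CLP ids are assigned
    in order of each cluster's earliest member timestamp.
    """
    if laying_fixes.empty:
        raise ValueError("cluster_laying_locations requires at least one laying fix")
    pts = laying_fixes[["x", "y"]].to_numpy(float)
    if len(pts) == 1:
        labels = np.array([1])
    else:
        cond = pdist(pts) if mode == "projected" else squareform(pairwise_distances(pts, mode), checks=False)
        labels = fcluster(linkage(cond, method="single"), t=linkage_radius_m, criterion="distance")

    ts = laying_fixes["timestamp"].to_numpy()
    order = sorted(np.unique(labels), key=lambda lab: ts[labels == lab].min())
    clps = []
    for cid, lab in enumerate(order, start=1):
        idx = np.flatnonzero(labels == lab)
        c = _mean_point(pts[idx], mode)
        clps.append(CLP(clp_id=cid, centroid_xy=(float(c[0]), float(c[1])),
                        member_index=[int(i) for i in idx]))
    return clps


def count_revisits(clps: list[CLP], recess_points: pd.DataFrame,
                   buffer_radius_m: float = BUFFER_RADIUS_M,
                   mode: str = "projected") -> tuple[list[CLP], pd.DataFrame]:
    """Assign recess fixes to CLP buffers and tally per-patch visit counts.

    A recess fix revisits a CLP when its distance to the patch centroid is
    <= ``buffer_radius_m``.  A fix inside overlapping buffers counts once,
    attributed to the nearest centroid (lowest clp_id on exact ties), so the
    proportion of recesses to CLPs can never exceed 1.  Returns CLPs with
    ``visit_count`` filled and the recess table with a ``clp_id`` column
    (pandas NA for recesses to no patch).
    """
    out = recess_points.copy()
    out["clp_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
    for c in clps:
        c.visit_count = 0
    rec = out.loc[out["is_recess"]] if "is_recess" in out else out
    if not clps or rec.empty:
        return clps, out
    cents = np.array([c.centroid_xy for c in clps], float)
    pts = rec[["x", "y"]].to_numpy(float)
    if mode == "projected":
        d = np.hypot(pts[:, None, 0] - cents[None, :, 0], pts[:, None, 1] - cents[None, :, 1])
    else:
        d = np.stack([distances_to_point(pts, c, mode) for c in cents], axis=1)
    nearest = d.argmin(axis=1)  # first (lowest clp_id) wins ties
    within = d[np.arange(len(pts)), nearest] <= buffer_radius_m
    ids = np.array([c.clp_id for c in clps])
    assigned = pd.array(np.where(within, ids[nearest], 0), dtype="Int64")
    assigned[~within] = pd.NA
    out.loc[rec.index, "clp_id"] = assigned
    counts = pd.Series(ids[nearest[within]]).value_counts()
    for c in clps:
        c.visit_count = int(counts.get(c.clp_id, 0))
    return clps, out


def summarize_prospecting(attempt_id: str, clps: list[CLP],
                          recess_points: pd.DataFrame) -> ProspectingSummary:
    """Per-attempt prospecting statistics from classified and assigned fixes."""
    rec = recess_points.loc[recess_points["is_recess"]] if "is_recess" in recess_points else recess_points
    total = len(rec)
    to_clp = int(rec["clp_id"].notna().sum()) if total else 0
    visited = int(rec["clp_id"].dropna().nunique()) if total else 0
    return ProspectingSummary(attempt_id=attempt_id, total_recesses=total,
                              recesses_to_clp=to_clp, n_clp_total=len(clps),
                              n_clp_visited=visited)


def clps_to_geojson(clps: list[CLP]) -> dict:
    """CLP centroids as a GeoJSON FeatureCollection."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(c.centroid_xy)},
                "properties": {"clp_id": c.clp_id, "n_members": c.n_members,
                               "visit_count": c.visit_count},
            }
            for c in clps
        ],
    }
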