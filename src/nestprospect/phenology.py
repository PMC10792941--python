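"""Segmentation of trajectories into laying and incubation windows.

Incubation onset is the first night a female's nightly (23:58:58) fix is at
the nest; laying onset is her earliest hourly fix strictly closer than 20 m
to the nest within the 20 days preceding incubation.  The on-nest radius is
27.5 m, the 90th-percentile positional error of the transmitters, reused
so no new spatial constant is introduced.

Nest sites were located in the field in the original workflow; here the
nest is either supplied (field-confirmed) or estimated as the geometric
median of the largest spatial cluster of nightly fixes.  A configurable
night-gap tolerance absorbs the occasional nightly fix displaced beyond
27.5 m by GPS error, so a single noisy night does not split an incubation
bout in two.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .gps import Trajectory, distances_to_point, pairwise_distances

ON_NEST_RADIUS_M = 27.5
NIGHTLY_TIME = dt.time(23, 58, 58)


@dataclass
class NestAttempt:
    """One nesting attempt for one female."""

    female_id: str
    attempt_index: int
    nest_xy: tuple[float, float]
    laying_onset: dt.date
    incubation_onset: dt.date
    incubation_end: dt.date
    fate: str = "unknown"  # success | fail | unknown

    @property
    def incubation_days(self) -> int:
        return (self.incubation_end - self.incubation_onset).days


def geometric_median(points: np.ndarray, tol: float = 1e-6, max_iter: int = 200) -> np.ndarray:
    """Weiszfeld's algorithm; falls back to the mean for degenerate inputs."""
    pts = np.atleast_2d(np.asarray(points, float))
    est = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.hypot(pts[:, 0] - est[0], pts[:, 1] - est[1])
        if (d < 1e-9).any():
            return pts[np.argmin(d)].copy()
        w = 1.0 / d
        new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.hypot(*(new - est)) < tol:
            return new
        est = new
    return est


def nightly_mask(fixes: pd.DataFrame, tolerance_min: float = 5.0) -> pd.Series:
    """True for fixes within ``tolerance_min`` minutes of the 23:58:58 schedule slot."""
    t = fixes["timestamp"]
    sec = t.dt.hour * 3600 + t.dt.minute * 60 + t.dt.second
    target = NIGHTLY_TIME.hour * 3600 + NIGHTLY_TIME.minute * 60 + NIGHTLY_TIME.second
    return (sec - target).abs() <= tolerance_min * 60


def _bouts(nights: list[dt.date], max_gap_nights: int) -> list[list[dt.date]]:
    """Split sorted night dates into bouts, tolerating gaps of <= max_gap_nights missed nights."""
    bouts: list[list[dt.date]] = []
    for night in nights:
        if bouts and (night - bouts[-1][-1]).days <= max_gap_nights + 1:
            bouts[-1].append(night)
        else:
            bouts.append([night])
    return bouts


def detect_incubation_bouts(
    trajectory: Trajectory,
    nest_xy=None,
    on_nest_radius_m: float = ON_NEST_RADIUS_M,
    tolerance_min: float = 5.0,
    max_gap_nights: int = 2,
    min_nights: int = 1,
    min_day_attendance: float = 0.5,
) -> list[dict]:
    """Find all candidate incubation bouts (ordered by onset) for one female.

    Returns a list of dicts with keys ``nest_xy``, ``incubation_onset``,
    ``incubation_end``, ``n_nights``.  Empty list when no nightly fix run
    qualifies.  When ``nest_xy`` is given the nest is taken as
    field-confirmed; otherwise candidate nests are the geometric medians of
    single-linkage clusters (at the on-nest radius) of nightly fixes.

    Incubating birds attend the nest by day as well as by night, so a bout
    must additionally show ``min_day_attendance`` of its hourly fixes
    on-nest — this rejects overnight roost clusters, which have essentially
    zero daytime attendance.
    """
    fixes = trajectory.fixes
    nmask = nightly_mask(fixes, tolerance_min)
    nights = fixes.loc[nmask]
    if nights.empty:
        return []
    pts = nights[["x", "y"]].to_numpy(float)

    if nest_xy is not None:
        candidates = [np.asarray(nest_xy, float)]
    else:
        if len(pts) == 1:
            labels = np.array([1])
        else:
            dm = pairwise_distances(pts, trajectory.mode)
            labels = fcluster(linkage(squareform(dm, checks=False), method="single"),
                              t=on_nest_radius_m, criterion="distance")
        candidates = []
        for lab in np.unique(labels):
            members = pts[labels == lab]
            if len(members) >= min_nights:
                candidates.append(geometric_median(members))

    hourly = fixes.loc[~nmask]
    hpts = hourly[["x", "y"]].to_numpy(float)
    hdates = hourly["timestamp"].dt.date

    bouts_out = []
    for cand in candidates:
        d = distances_to_point(pts, cand, trajectory.mode)
        on = d <= on_nest_radius_m
        night_dates = sorted(nights.loc[on, "timestamp"].dt.date.unique())
        for bout in _bouts(night_dates, max_gap_nights):
            if len(bout) < min_nights:
                continue
            in_bout = on & nights["timestamp"].dt.date.isin(bout).to_numpy()
            est = cand if nest_xy is not None else geometric_median(pts[in_bout])
            span = (hdates >= bout[0]) & (hdates <= bout[-1])
            if span.any():
                hd = distances_to_point(hpts[span.to_numpy()], est, trajectory.mode)
                if np.mean(hd <= on_nest_radius_m) < min_day_attendance:
                    continue
            # a noisy nightly fix can hide the true first night: pull the
            # onset back while the preceding day was spent on the nest
            onset = bout[0]
            while True:
                prev = onset - dt.timedelta(days=1)
                day = (hdates == prev).to_numpy()
                if not day.any():
                    break
                hd = distances_to_point(hpts[day], est, trajectory.mode)
                if np.mean(hd <= on_nest_radius_m) < max(min_day_attendance, 0.5):
                    break
                onset = prev
            if onset < bout[0]:
                bout = [onset, *bout]
            bouts_out.append({
                "nest_xy": (float(est[0]), float(est[1])),
                "incubation_onset": bout[0],
                "incubation_end": bout[-1] + dt.timedelta(days=1),
                "n_nights": len(bout),
            })
    bouts_out.sort(key=lambda b: b["incubation_onset"])
    # overlapping candidate bouts (e.g. two nearby nightly clusters) keep the longer
    kept: list[dict] = []
    for b in bouts_out:
        if kept and b["incubation_onset"] < kept[-1]["incubation_end"]:
            if b["n_nights"] > kept[-1]["n_nights"]:
                kept[-1] = b
        else:
            kept.append(b)
    return kept


def detect_incubation_onset(trajectory: Trajectory, nest_xy=None, **kwargs):
    """The longest incubation bout, or None when no nightly run qualifies."""
    bouts = detect_incubation_bouts(trajectory, nest_xy=nest_xy, **kwargs)
    if not bouts:
        return None
    return max(bouts, key=lambda b: b["n_nights"])


def detect_laying_onset(
    trajectory: Trajectory,
    nest_xy,
    incubation_onset: dt.date,
    lookback_days: int = 20,
    visit_radius_m: float = 20.0,
    tolerance_min: float = 5.0,
) -> dt.date:
    """Date of the first nest visit in the pre-incubation window.

    A visit is an hourly (non-nightly) fix strictly closer than
    ``visit_radius_m`` to the nest, within the ``lookback_days`` days before
    ``incubation_onset``.  When no such fix exists the laying onset falls
    back to the incubation onset.
    """
    fixes = trajectory.fixes
    hourly = fixes.loc[~nightly_mask(fixes, tolerance_min)]
    dates = hourly["timestamp"].dt.date
    window = (dates >= incubation_onset - dt.timedelta(days=lookback_days)) & (dates < incubation_onset)
    cand = hourly.loc[window]
    if cand.empty:
        return incubation_onset
    d = distances_to_point(cand[["x", "y"]].to_numpy(float), np.asarray(nest_xy, float), trajectory.mode)
    visits = cand.loc[d < visit_radius_m]
    if visits.empty:
        return incubation_onset
    return visits["timestamp"].dt.date.min()


def derive_attempts(trajectory: Trajectory, nest_xy=None, lookback_days: int = 20,
                    visit_radius_m: float = 20.0, **bout_kwargs) -> list[NestAttempt]:
    """Full segmentation for one female: bouts -> attempts ordered by onset."""
    attempts = []
    for i, bout in enumerate(detect_incubation_bouts(trajectory, nest_xy=nest_xy, **bout_kwargs), start=1):
        laying = detect_laying_onset(trajectory, bout["nest_xy"], bout["incubation_onset"],
                                     lookback_days=lookback_days, visit_radius_m=visit_radius_m)
        attempts.append(NestAttempt(
            female_id=trajectory.female_id, attempt_index=i, nest_xy=bout["nest_xy"],
            laying_onset=laying, incubation_onset=bout["incubation_onset"],
            incubation_end=bout["incubation_end"]))
    return attempts


def filter_attempts(attempts: list[NestAttempt], min_incubation_days: int = 3):
    """Drop attempts incubated for fewer than ``min_incubation_days`` whole days.

    The boundary is inclusive on the kept side: exactly 3 days is kept.
    Returns (kept, removed).
    """
    kept = [a for a in attempts if a.incubation_days >= min_incubation_days]
    removed = [a for a in attempts if a.incubation_days < min_incubation_days]
    return kept, removed
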