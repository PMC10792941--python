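"""Shared fixtures: small synthetic populations and hand-built trajectories."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from nestprospect.gps import Trajectory
from nestprospect.pipeline import segment_attempts
from nestprospect.synthetic import SimConfig, generate_population


def make_trajectory(rows, female_id="F001", mode="projected"):
    """Build a Trajectory from (datetime, x, y[, dop]) tuples."""
    recs = [(r[0], r[1], r[2], r[3] if len(r) > 3 else 2.0) for r in rows]
    df = pd.DataFrame(recs, columns=["timestamp", "x", "y", "dop"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return Trajectory(female_id, df, mode=mode)


@pytest.fixture(scope="session")
def noise_free_attempt():
    """One attempt with zero GPS noise: every rule is exactly recoverable."""
    cfg = SimConfig(n_females=1, gps_noise_sd=0.0, seed=101)
    land, roads, trajs, fates, truths = generate_population(cfg)
    return trajs[0], truths[0]


@pytest.fixture(scope="session")
def small_population():
    """Ten females at the default 10-m noise, segmented against truth."""
    cfg = SimConfig(n_females=10, seed=33)
    land, roads, trajs, fates, truths = generate_population(cfg)
    kept, removed, cleaned, counts = segment_attempts(trajs, truths)
    return {"landscape": land, "roads": roads, "trajectories": trajs,
            "fates": fates, "truths": {t.female_id: t for t in truths},
            "kept": kept, "cleaned": cleaned, "counts": counts}


@pytest.fixture(scope="session")
def recovery_population():
    """100 attempts at 10-m GPS noise for the segmentation/prospecting
    recovery experiments (two independent 50-female populations)."""
    out = []
    for seed in (11, 29):
        cfg = SimConfig(n_females=50, seed=seed, p_revisit=0.57)
        land, roads, trajs, fates, truths = generate_population(cfg)
        kept, removed, cleaned, counts = segment_attempts(trajs, truths)
        out.append({"kept": kept, "cleaned": cleaned,
                    "truths": {t.female_id: t for t in truths}})
    return out


def brute_force_single_linkage(points: np.ndarray, radius: float) -> list[set]:
    """Union-find over all pairwise distances: the clustering oracle."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def incubation_start(truth) -> dt.date:
    return truth.true_incubation_onset
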