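import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestprospect import prospecting

from conftest import brute_force_single_linkage


def points_df(xy, t0=dt.datetime(2020, 4, 1, 5)):
    xy = np.atleast_2d(np.asarray(xy, float))
    return pd.DataFrame({
        "timestamp": pd.to_datetime([t0 + dt.timedelta(hours=i) for i in range(len(xy))]),
        "x": xy[:, 0], "y": xy[:, 1]})


def recess_df(xy, is_recess=None):
    df = points_df(xy)
    df["is_recess"] = True if is_recess is None else is_recess
    return df


class TestClassifyRecesses:
    def test_threshold_boundary(self):
        df = prospecting.classify_recesses(points_df([[27.5, 0], [27.6, 0]]), (0, 0))
        assert list(df["is_recess"]) == [False, True]
        assert df["distance_to_nest"].tolist() == [27.5, 27.6]

    def test_missing_nest_raises(self):
        with pytest.raises(ValueError):
            prospecting.classify_recesses(points_df([[0, 0]]), None)

    def test_noise_free_generator_agreement(self, noise_free_attempt):
        traj, truth = noise_free_attempt
        dates = traj.fixes["timestamp"].dt.date
        incub = (dates >= truth.true_incubation_onset) & (dates < truth.true_incubation_end)
        df = prospecting.classify_recesses(traj.fixes.loc[incub], truth.true_nest_xy)
        want = [lb == "recess" for lb, i in zip(truth.labels, incub) if i]
        assert list(df["is_recess"]) == want


class TestClusterLayingLocations:
    def test_single_fix_single_singleton(self):
        clps = prospecting.cluster_laying_locations(points_df([[10, 20]]))
        assert len(clps) == 1 and clps[0].centroid_xy == (10.0, 20.0)

    def test_linkage_boundary_inclusive(self):
        one = prospecting.cluster_laying_locations(points_df([[0, 0], [150.0, 0]]))
        two = prospecting.cluster_laying_locations(points_df([[0, 0], [150.1, 0]]))
        assert len(one) == 1 and len(two) == 2

    def test_ids_follow_earliest_member_timestamp(self):
        # second cluster in space appears first in time
        clps = prospecting.cluster_laying_locations(points_df([[500, 0], [0, 0], [501, 1]]))
        assert clps[0].member_index == [0, 2] and clps[0].clp_id == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1500, (120, 2))
        clps = prospecting.cluster_laying_locations(points_df(pts))
        got = {frozenset(c.member_index) for c in clps}
        want = {frozenset(g) for g in brute_force_single_linkage(pts, 150.0)}
        assert got == want

    def test_partition_and_centroid(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 800, (60, 2))
        clps = prospecting.cluster_laying_locations(points_df(pts))
        members = sorted(i for c in clps for i in c.member_index)
        assert members == list(range(60))
        for c in clps:
            np.testing.assert_allclose(c.centroid_xy, pts[c.member_index].mean(axis=0))


class TestCountRevisits:
    def test_buffer_boundary_inclusive(self):
        clps = prospecting.cluster_laying_locations(points_df([[0, 0]]))
        clps, rec = prospecting.count_revisits(clps, recess_df([[45.0, 0], [45.1, 0]]))
        assert clps[0].visit_count == 1
        assert rec["clp_id"].iloc[0] == 1 and pd.isna(rec["clp_id"].iloc[1])

    def test_tie_goes_to_lower_id_and_counts_once(self):
        clps = prospecting.cluster_laying_locations(points_df([[0, 0], [600, 0]]))
        clps, rec = prospecting.count_revisits(clps, recess_df([[300.0, 0]]),
                                               buffer_radius_m=301.0)
        assert rec["clp_id"].tolist() == [1]
        assert (clps[0].visit_count, clps[1].visit_count) == (1, 0)

    def test_empty_clp_list(self):
        clps, rec = prospecting.count_revisits([], recess_df([[0, 0]]))
        assert rec["clp_id"].isna().all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        lay = rng.uniform(0, 3000, (40, 2))
        rec_xy = rng.uniform(0, 3000, (300, 2))
        clps = prospecting.cluster_laying_locations(points_df(lay))
        clps, rec = prospecting.count_revisits(clps, recess_df(rec_xy))
        cents = np.array([c.centroid_xy for c in clps])
        for k, p in enumerate(rec_xy):
            d = np.hypot(cents[:, 0] - p[0], cents[:, 1] - p[1])
            if d.min() <= 45.0:
                assert rec["clp_id"].iloc[k] == clps[int(d.argmin())].clp_id
            else:
                assert pd.isna(rec["clp_id"].iloc[k])
        for c in clps:
            assert c.visit_count == int((rec["clp_id"] == c.clp_id).sum())


class TestSummarize:
    def test_zero_recesses(self):
        clps = prospecting.cluster_laying_locations(points_df([[0, 0]]))
        s = prospecting.summarize_prospecting("a", clps, recess_df(np.empty((0, 2))))
        assert s.total_recesses == 0 and s.proportion_to_clp == 0.0 and s.n_clp_visited == 0

    def test_saturation(self):
        rng = np.random.default_rng(1)
        lay = np.array([[i * 400.0, 0.0] for i in range(9)])
        clps = prospecting.cluster_laying_locations(points_df(lay))
        rec_xy = np.repeat(lay[:5], 8, axis=0) + rng.uniform(-5, 5, (40, 2))
        clps, rec = prospecting.count_revisits(clps, recess_df(rec_xy))
        s = prospecting.summarize_prospecting("a", clps, rec)
        assert s.proportion_to_clp == 1.0
        assert (s.n_clp_visited, s.n_clp_total) == (5, 9)


class TestProperties:
    @settings(derandomize=True, max_examples=25)
    @given(st.tuples(st.floats(-1e5, 1e5), st.floats(-1e5, 1e5)))
    def test_translation_invariance(self, shift):
        rng = np.random.default_rng(5)
        lay = rng.uniform(0, 2000, (30, 2))
        rec_xy = rng.uniform(0, 2000, (80, 2))

        def summarize(off):
            clps = prospecting.cluster_laying_locations(points_df(lay + off))
            clps, rec = prospecting.count_revisits(clps, recess_df(rec_xy + off))
            return prospecting.summarize_prospecting("a", clps, rec)

        a, b = summarize(np.zeros(2)), summarize(np.asarray(shift))
        assert (a.total_recesses, a.recesses_to_clp, a.n_clp_total, a.n_clp_visited) == \
               (b.total_recesses, b.recesses_to_clp, b.n_clp_total, b.n_clp_visited)

    def test_monotone_in_buffer_radius(self):
        rng = np.random.default_rng(6)
        lay = rng.uniform(0, 2000, (30, 2))
        rec_xy = rng.uniform(0, 2000, (80, 2))
        clps0 = prospecting.cluster_laying_locations(points_df(lay))
        prev_prop, prev_vis = -1.0, -1
        for r in (15.0, 45.0, 75.0, 150.0):
            clps, rec = prospecting.count_revisits(clps0, recess_df(rec_xy), buffer_radius_m=r)
            s = prospecting.summarize_prospecting("a", clps, rec)
            assert s.proportion_to_clp >= prev_prop and s.n_clp_visited >= prev_vis
            prev_prop, prev_vis = s.proportion_to_clp, s.n_clp_visited

    def test_n_clp_nonincreasing_in_linkage_radius(self):
        rng = np.random.default_rng(7)
        lay = rng.uniform(0, 2000, (60, 2))
        prev = np.inf
        for r in (75.0, 150.0, 300.0, 600.0):
            n = len(prospecting.cluster_laying_locations(points_df(lay), linkage_radius_m=r))
            assert n <= prev
            prev = n
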