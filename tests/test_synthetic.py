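import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from nestprospect import synthetic as S
from nestprospect.gps import distances_to_point


def attempt(cfg, seed=5, landscape=None):
    if landscape is None:
        landscape, _ = S.generate_landscape(seed=1)
    return S.generate_attempt(cfg, landscape, "F001", np.random.default_rng(seed))


class TestLandscape:
    def test_degenerate_mix_all_pine(self):
        r, _ = S.generate_landscape(extent=(900, 900), class_mix=[0, 1, 0, 0, 0, 0], seed=0)
        assert (r.grid == 2).all()
        from nestprospect.landscape import distance_surface
        assert (distance_surface(r, 2) == 0).all()

    def test_grid_arithmetic(self):
        r, _ = S.generate_landscape(extent=(3000, 3000), resolution=30, seed=0)
        assert r.shape == (100, 100) and r.grid.size == 10_000

    def test_seed_determinism(self):
        a, ra = S.generate_landscape(seed=7)
        b, rb = S.generate_landscape(seed=7)
        np.testing.assert_array_equal(a.grid, b.grid)
        assert all(x.equals_exact(y, 0) for x, y in zip(ra, rb))

    def test_bad_config_rejected(self):
        with pytest.raises(S.ConfigError):
            S.generate_landscape(extent=(-10, 100), seed=0)
        with pytest.raises(S.ConfigError):
            S.generate_landscape(extent=(1000, 1000), resolution=33, seed=0)


class TestSchedule:
    def test_fix_count_matches_enumerated_schedule(self):
        cfg = S.SimConfig(laying_days=12, incubation_days=28, n_females=1)
        traj, truth = attempt(cfg)
        # independent enumeration of the transmitter schedule
        expected = set()
        for d in range(40):
            day = cfg.start_date + dt.timedelta(days=d)
            for h in range(5, 21):
                expected.add(dt.datetime.combine(day, dt.time(h)))
            expected.add(dt.datetime.combine(day, dt.time(23, 58, 58)))
        got = set(traj.fixes["timestamp"])
        assert got == {pd.Timestamp(e) for e in expected}
        assert len(traj) == 40 * 17

    def test_schedule_closure(self):
        traj, _ = attempt(S.SimConfig())
        t = traj.fixes["timestamp"]
        hourly = (t.dt.minute == 0) & (t.dt.second == 0) & t.dt.hour.between(5, 20)
        nightly = (t.dt.hour == 23) & (t.dt.minute == 58) & (t.dt.second == 58)
        assert (hourly | nightly).all()


class TestAttemptGeometry:
    def test_zero_noise_zero_recess_all_on_nest(self):
        cfg = S.SimConfig(gps_noise_sd=0.0, recesses_per_day=0.0)
        traj, truth = attempt(cfg)
        dates = traj.fixes["timestamp"].dt.date
        inc = traj.fixes.loc[(dates >= truth.true_incubation_onset)]
        d = distances_to_point(inc[["x", "y"]].to_numpy(), truth.true_nest_xy)
        assert d.max() == 0.0

    def test_zero_noise_labels_match_geometry(self):
        cfg = S.SimConfig(gps_noise_sd=0.0)
        traj, truth = attempt(cfg)
        d = distances_to_point(traj.fixes[["x", "y"]].to_numpy(), truth.true_nest_xy)
        for dist, lb in zip(d, truth.labels):
            if lb == "on-nest":
                assert dist == 0.0
            elif lb == "recess":
                assert dist > 27.5

    def test_labels_partition_fixes(self):
        traj, truth = attempt(S.SimConfig())
        assert len(truth.labels) == len(traj)
        assert set(truth.labels) <= {"laying-forage", "nest-visit", "roost", "on-nest", "recess"}

    def test_p_revisit_boundaries(self):
        t1 = attempt(S.SimConfig(p_revisit=1.0), seed=8)[1]
        assert all(isinstance(t, int) for t in t1.recess_target if t is not None)
        t0 = attempt(S.SimConfig(p_revisit=0.0), seed=8)[1]
        assert all(t == "fresh" for t in t0.recess_target if t is not None)

    def test_recess_targets_within_patch_radius_before_noise(self):
        cfg = S.SimConfig(gps_noise_sd=0.0, p_revisit=1.0)
        traj, truth = attempt(cfg)
        for (x, y), tgt in zip(traj.fixes[["x", "y"]].to_numpy(), truth.recess_target):
            if isinstance(tgt, int):
                c = truth.patch_centers[tgt]
                assert np.hypot(x - c[0], y - c[1]) <= 20.0 + 1e-9

    def test_determinism(self):
        a = attempt(S.SimConfig(), seed=9)[0].fixes
        b = attempt(S.SimConfig(), seed=9)[0].fixes
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(S.ConfigError):
            S.SimConfig(p_revisit=1.5)
        with pytest.raises(S.ConfigError):
            S.SimConfig(gps_noise_sd=-1.0)

    def test_geographic_mode_distances_consistent(self):
        cfg = S.SimConfig(gps_noise_sd=0.0, coordinate_mode="geographic")
        traj, truth = attempt(cfg)
        nest_ll = S.planar_to_lonlat(truth.true_nest_xy)[0]
        d = distances_to_point(traj.fixes[["x", "y"]].to_numpy(), nest_ll, "geographic")
        for dist, lb in zip(d, truth.labels):
            if lb == "on-nest":
                assert dist < 0.5  # projection round-trip error only
            elif lb == "recess":
                assert dist > 27.5


class TestSimulateFates:
    def test_null_model_near_half(self):
        rng = np.random.default_rng(0)
        cfg = S.SimConfig(fate_intercept=0.0, fate_beta_prop=0.0, fate_beta_nclp=0.0,
                          random_intercept_sd=0.0)
        cov = pd.DataFrame({"female_id": [f"F{i}" for i in range(2000)],
                            "proportion": rng.random(2000), "n_clp": rng.integers(0, 9, 2000)})
        out = S.simulate_fates(cov, cfg, rng)
        frac = (out["fate"] == "success").mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(2000)  # binomial 3-sigma

    def test_saturating_intercept(self):
        rng = np.random.default_rng(0)
        cfg = S.SimConfig(fate_intercept=50.0, fate_beta_prop=0.0, fate_beta_nclp=0.0,
                          random_intercept_sd=0.0)
        cov = pd.DataFrame({"female_id": ["F1", "F2"] * 50,
                            "proportion": rng.random(100), "n_clp": rng.integers(0, 9, 100)})
        assert (S.simulate_fates(cov, cfg, rng)["fate"] == "success").all()

    def test_closed_form_logistic_probability(self):
        # alpha=0, beta_nclp=1, z fixed at +/-1, no random effect:
        # success probability of the +1 group is logit^-1(1) ~ 0.7311
        rng = np.random.default_rng(1)
        n = 4000
        cfg = S.SimConfig(fate_intercept=0.0, fate_beta_prop=0.0, fate_beta_nclp=1.0,
                          random_intercept_sd=0.0)
        cov = pd.DataFrame({"female_id": [f"F{i}" for i in range(n)],
                            "proportion": rng.random(n),
                            "n_clp": np.tile([0, 2], n // 2)})
        out = S.simulate_fates(cov, cfg, rng)
        hi = out.loc[out["n_clp"] == 2, "p_success"]
        z = (2 - 1.0) / np.std(np.tile([0, 2], n // 2), ddof=1)
        assert np.allclose(hi, expit(z))
        assert expit(1.0) == pytest.approx(0.7311, abs=1e-4)
        frac = (out.loc[out["n_clp"] == 2, "fate"] == "success").mean()
        assert abs(frac - expit(z)) < 3 * np.sqrt(0.25 / (n / 2))

    def test_nonfinite_covariates_rejected(self):
        cfg = S.SimConfig()
        cov = pd.DataFrame({"female_id": ["F1", "F2"], "proportion": [0.5, np.nan],
                            "n_clp": [1, 2]})
        with pytest.raises(ValueError):
            S.simulate_fates(cov, cfg, np.random.default_rng(0))


def test_population_determinism_and_shared_intercepts():
    cfg = S.SimConfig(n_females=3, attempts_per_female=2, seed=21)
    _, _, trajs_a, fates_a, truths_a = S.generate_population(cfg)
    _, _, trajs_b, fates_b, _ = S.generate_population(cfg)
    pd.testing.assert_frame_equal(trajs_a[0].fixes, trajs_b[0].fixes)
    pd.testing.assert_frame_equal(fates_a, fates_b)
    assert len(truths_a) == 6
    # renesting attempts follow the first attempt in time
    assert truths_a[1].true_laying_onset > truths_a[0].true_incubation_end
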