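import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from nestprospect import models as M


class TestStandardize:
    def test_z_mode_hand_computed(self):
        z, ctr, scl = M.standardize([1.0, 2.0, 3.0], "z")
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])  # sample sd = 1.0
        assert (ctr, scl) == (2.0, 1.0)

    def test_2sd_mode_halves_spread(self):
        rng = np.random.default_rng(0)
        z, _, _ = M.standardize(rng.normal(3, 7, 500), "2sd")
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(0.5)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            M.standardize([4.0, 4.0, 4.0])


class TestCollinearityScreen:
    def test_orthogonal_all_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        assert M.screen_collinearity(df) == list("abcd")

    def test_duplicate_column_drops_exactly_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        kept = M.screen_collinearity(df)
        assert len(kept) == 2 and "c" in kept

    def test_hand_computed_five_covariate_fixture(self):
        rng = np.random.default_rng(3)
        n = 400
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)  # r ~ 0.8 with a
        rest = rng.normal(size=(n, 3))
        df = pd.DataFrame({"a": a, "b": b, "c": rest[:, 0], "d": rest[:, 1], "e": rest[:, 2]})
        r = np.corrcoef(df.to_numpy(), rowvar=False)
        assert abs(r[0, 1]) > 0.6  # fixture sanity
        kept = M.screen_collinearity(df)
        assert len(kept) == 4
        assert ("a" in kept) ^ ("b" in kept)  # exactly one of the correlated pair survives
        assert {"c", "d", "e"} <= set(kept)

    def test_constant_dropped_with_warning(self):
        df = pd.DataFrame({"a": np.arange(10.0), "k": np.ones(10)})
        with pytest.warns(UserWarning):
            kept = M.screen_collinearity(df)
        assert kept == ["a"]


class TestProbabilityOfDirection:
    def test_all_positive(self):
        assert M.probability_of_direction([0.1, 2.0, 3.0]) == 1.0

    def test_antithetic_half(self):
        d = np.r_[np.arange(1, 50), -np.arange(1, 50)]
        assert M.probability_of_direction(d) == 0.5

    def test_direct_count(self):
        assert M.probability_of_direction([-1.0, 2.0, 3.0, 4.0]) == 0.75

    def test_sign_and_order_invariance(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.3, 1, 500)
        assert M.probability_of_direction(d) == M.probability_of_direction(-d)
        assert M.probability_of_direction(d) == M.probability_of_direction(rng.permutation(d))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.probability_of_direction([])


class TestRhat:
    def test_identical_chains_exactly_one(self):
        c = np.tile(np.random.default_rng(0).normal(size=500), (4, 1))
        assert M.rhat(c) == 1.0

    def test_separated_means_flagged(self):
        rng = np.random.default_rng(1)
        c = np.vstack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert M.rhat(c) > 1.1

    def test_white_noise_calibration(self):
        ok = 0
        for seed in range(100):
            c = np.random.default_rng(seed).normal(size=(4, 2000))
            ok += M.rhat(c) < 1.01
        assert ok >= 95

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            M.rhat(np.zeros((1, 100)))

    def test_agrees_with_arviz(self):
        import arviz as az
        rng = np.random.default_rng(5)
        c = rng.normal(size=(4, 1000)) + rng.normal(0, 0.3, size=(4, 1))
        ours = M.rhat(c)
        theirs = float(az.rhat(az.convert_to_dataset(c), method="split")["x"].values)
        assert ours == pytest.approx(theirs, abs=0.01)


def simulate_fate_data(seed, n=300, beta=(0.3, 0.8), sigma_b=1.0):
    rng = np.random.default_rng(seed)
    nf = n // 2
    fid = np.repeat([f"F{i}" for i in range(nf)], 2)
    b = np.repeat(rng.normal(0, sigma_b, nf), 2)
    z1, z2 = rng.normal(size=n), rng.normal(size=n)
    y = (rng.random(n) < expit(beta[0] * z1 + beta[1] * z2 + b)).astype(int)
    return y, pd.DataFrame({"proportion_to_clp": z1, "n_clp_visited": z2}), fid


class TestNestFateModel:
    @pytest.fixture(scope="class")
    def fit(self):
        y, cov, fid = simulate_fate_data(10)
        return M.fit_nest_fate(y, cov, fid, chains=4, iterations=2000,
                               burn_in=500, seed=3), y, cov, fid

    def test_recovers_signal_and_converges(self, fit):
        post, y, cov, fid = fit
        t = post.table()
        assert post.converged
        assert t.loc["n_clp_visited", "ci_2.5"] < 0.8 < t.loc["n_clp_visited", "ci_97.5"]
        assert t.loc["n_clp_visited", "pd"] > 0.975

    def test_interval_brackets_mean(self, fit):
        post = fit[0]
        assert np.all(post.ci_lower <= post.mean) and np.all(post.mean <= post.ci_upper)

    def test_marginal_effect_zero_for_null_coefficient(self):
        # a posterior concentrated at beta = 0 must give a zero AME
        y, cov, fid = simulate_fate_data(13, n=40)
        post = M.fit_nest_fate(y, cov, fid, chains=2, iterations=400, burn_in=100, seed=2)
        post.draws["proportion_to_clp"] = np.zeros_like(post.draws["proportion_to_clp"])
        ame = M.marginal_effect(post, cov, fid, covariate="proportion_to_clp")
        assert ame == 0.0

    def test_marginal_effect_small_beta_closed_form(self):
        # single row at p = 0.5: AME ~ 0.25 * beta * delta_std (logistic slope)
        y, cov, fid = simulate_fate_data(11, n=40)
        post = M.fit_nest_fate(y, cov, fid, chains=2, iterations=400, burn_in=100, seed=1)
        beta = 0.05
        for nm in post.draws:
            post.draws[nm] = np.zeros_like(post.draws[nm])
        post.draws["n_clp_visited"] += beta
        row = cov.iloc[[0]].copy()
        row[:] = [[post.scalers["proportion_to_clp"][0], post.scalers["n_clp_visited"][0]]]
        delta_std = 1.0 / post.scalers["n_clp_visited"][1]
        ame = M.marginal_effect(post, row, [fid[0]], covariate="n_clp_visited")
        assert ame == pytest.approx(100 * 0.25 * beta * delta_std, rel=0.01)

    def test_seed_determinism(self):
        y, cov, fid = simulate_fate_data(12, n=100)
        a = M.fit_nest_fate(y, cov, fid, chains=2, iterations=300, burn_in=100, seed=5)
        b = M.fit_nest_fate(y, cov, fid, chains=2, iterations=300, burn_in=100, seed=5)
        np.testing.assert_array_equal(a.mean, b.mean)


class TestRSF:
    @staticmethod
    def simulate(seed, beta_water=-1.5, sigma_b=0.5, nf=20, n_per=150):
        rng = np.random.default_rng(seed)
        fid = np.repeat([f"F{i}" for i in range(nf)], n_per)
        b = np.repeat(rng.normal(0, sigma_b, nf), n_per)
        water = rng.normal(size=nf * n_per)
        pine = rng.normal(size=nf * n_per)
        # covariates enter on the 2-SD scale, matching the fit
        eta = -1.5 + beta_water * (water - water.mean()) / (2 * water.std(ddof=1)) + b
        y = (rng.random(nf * n_per) < expit(eta)).astype(int)
        return pd.DataFrame({"used": y, "water": water, "pine": pine, "fid": fid})

    def test_directional_recovery(self):
        df = self.simulate(0)
        fit = M.fit_rsf(df, ["water", "pine"], df["fid"])
        t = fit.table()
        assert t.loc["water", "beta"] < 0
        assert abs(t.loc["water", "beta"]) > 1.96 * t.loc["water", "se"]
        assert abs(t.loc["pine", "beta"]) < 2 * t.loc["pine", "se"]

    def test_agrees_with_lme4_glmer(self, tmp_path):
        df = self.simulate(1)
        fit = M.fit_rsf(df, ["water", "pine"], df["fid"])
        csv = tmp_path / "ua.csv"
        df.to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e", f"""
            d <- read.csv('{csv}')
            d$w <- (d$water-mean(d$water))/(2*sd(d$water))
            d$p <- (d$pine-mean(d$pine))/(2*sd(d$pine))
            m <- lme4::glmer(used ~ w + p + (1|fid), data=d, family=binomial)
            co <- summary(m)$coefficients
            cat(co[,1], co[,2], unlist(lme4::VarCorr(m)), sep=',')
            """],
            capture_output=True, text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        vals = [float(v) for v in r.stdout.strip().split(",")]
        np.testing.assert_allclose(fit.beta, vals[0:3], atol=0.02)
        np.testing.assert_allclose(fit.se, vals[3:6], atol=0.01)
        assert fit.sigma_b2 == pytest.approx(vals[6], abs=0.05)

    def test_variance_recovery_order_of_magnitude(self):
        df = self.simulate(2, sigma_b=1.0, nf=60, n_per=100)
        fit = M.fit_rsf(df, ["water", "pine"], df["fid"])
        assert 0.5 <= fit.sigma_b2 <= 2.0

    def test_collinear_covariate_dropped_before_fit(self):
        df = self.simulate(3)
        df["water2"] = df["water"] * 1.0000001
        fit = M.fit_rsf(df, ["water", "water2", "pine"], df["fid"])
        assert len(fit.covariates) == 2 and fit.dropped != []

    def test_complete_separation_raises(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.normal(size=n)
        df = pd.DataFrame({"used": (x > 0).astype(int), "x": x,
                           "fid": np.repeat(["a", "b"], n // 2)})
        with pytest.raises(M.SeparationError):
            M.fit_rsf(df, ["x"], df["fid"])
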