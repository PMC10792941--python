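"""Nest-fate and resource-selection models.

Two fitted models close the pipeline:

* **Nest fate** — Bayesian random-intercept logistic regression.  Fate
  (success/fail) is Bernoulli with logit ``alpha + beta . z + b_female``,
  ``b_f ~ Normal(0, sigma_b^2)``.  Covariates (proportion of recesses to
  CLPs, number of CLPs visited) are standardized to unit sample SD.
  Posterior sampling is an adaptive random-walk Metropolis-within-Gibbs
  sampler with weakly informative priors — Normal(0, 2.5^2) on coefficients
  and half-Normal(0, 2) on sigma_b — run as 4 chains of 8000 iterations
  with the first 1000 discarded per chain.  Summaries: posterior mean, 95%
  equal-tailed credible interval, probability of direction, split R-hat
  (convergence taken as all R-hat < 1.1).

* **Resource selection (RSF)** — used/available logistic GLMM (third-order
  selection: recess fixes assigned to CLPs versus 500 uniformly sampled
  points per 95% incubation range), random intercept per female, fitted by
  maximum likelihood with adaptive Gauss-Hermite integration of the random
  effect.  Covariates are rescaled by twice their SD after a Pearson
  collinearity screen at |r| > 0.60.  A negative coefficient on a distance
  covariate means selection for proximity to that feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit


# ---------------------------------------------------------------- utilities

def standardize(x, mode: str = "z") -> tuple[np.ndarray, float, float]:
    """Center and rescale a covariate; returns (z, center, scale).

    mode "z": unit sample SD (n-1 denominator).  mode "2sd": half-unit SD —
    dividing by twice the SD makes continuous and binary effects comparable.
    """
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant covariate")
    mult = {"z": 1.0, "2sd": 2.0}[mode]
    return (x - x.mean()) / (mult * sd), float(x.mean()), float(mult * sd)


def screen_collinearity(covariates: pd.DataFrame, r_max: float = 0.60) -> list[str]:
    """Greedy Pearson collinearity screen.

    Constant columns are dropped with a warning (correlation undefined).
    While any |r| exceeds ``r_max``, the covariate with the largest mean
    absolute correlation against the others is removed (ties broken by
    column order).  Returns the kept column names, original order.
    """
    cols = list(covariates.columns)
    X = covariates.to_numpy(float)
    keep = []
    for k, c in enumerate(cols):
        if X[:, k].std() == 0:
            warnings.warn(f"covariate {c!r} is constant; dropped from the screen")
        else:
            keep.append(c)
    while len(keep) > 1:
        r = np.abs(np.corrcoef(covariates[keep].to_numpy(float), rowvar=False))
        np.fill_diagonal(r, 0.0)
        if r.max() <= r_max:
            break
        keep.pop(int(np.argmax(r.mean(axis=1))))
    return keep


def probability_of_direction(draws) -> float:
    """pd = larger of the posterior fractions strictly above / below zero
    (exact zeros split evenly); lies in [0.5, 1]."""
    d = np.asarray(draws, float).ravel()
    if d.size == 0:
        raise ValueError("probability_of_direction needs at least one draw")
    half_zero = 0.5 * np.mean(d == 0)
    return float(max(np.mean(d > 0) + half_zero, np.mean(d < 0) + half_zero))


def rhat(chains) -> float:
    """Split potential-scale-reduction statistic.

    Each chain is split in half; R-hat compares between- and within-half
    variances.  Bit-identical chains are the degenerate perfectly-mixed
    case and return exactly 1.0.
    """
    c = np.asarray(chains, float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("rhat needs >= 2 chains of equal length")
    if c.shape[1] < 4:
        raise ValueError("chains too short for split R-hat")
    if all(np.array_equal(c[0], row) for row in c):
        return 1.0
    half = c.shape[1] // 2
    splits = np.vstack([c[:, :half], c[:, half:2 * half]])
    n = splits.shape[1]
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ------------------------------------------------------------- nest fate MCMC

@dataclass
class PosteriorSummary:
    """Posterior summaries for the nest-fate model."""

    params: list[str]
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pd: np.ndarray
    rhat: np.ndarray
    sigma_b_mean: float
    sigma_b2_mean: float
    converged: bool
    draws: dict = field(repr=False, default_factory=dict)  # param -> (chains, iters)
    scalers: dict = field(default_factory=dict)  # covariate -> (center, scale)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "ci_2.5": self.ci_lower,
                             "ci_97.5": self.ci_upper, "pd": self.pd,
                             "rhat": self.rhat}, index=self.params)


def _loglik_rows(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return log_expit(np.where(y == 1, eta, -eta))


def fit_nest_fate(fates, covariates: pd.DataFrame, female_ids, chains: int = 4,
                  iterations: int = 8000, burn_in: int = 1000, seed: int = 0,
                  prior_sd_beta: float = 2.5, prior_sd_sigma: float = 2.0,
                  adapt: bool = True) -> PosteriorSummary:
    """Fit the Bernoulli nest-fate model by adaptive random-walk MCMC.

    ``fates`` is binary (1 = success) or "success"/"fail" strings;
    covariates are standardized internally to unit sample SD and reported
    on that scale.  Non-convergence (any split R-hat >= 1.1) produces a
    result flagged unconverged plus a warning, never an exception.
    """
    y = np.asarray([1 if f in (1, True, "success") else 0 for f in fates], int)
    names = list(covariates.columns)
    Z = np.empty((len(y), len(names)))
    scalers = {}
    for k, c in enumerate(names):
        Z[:, k], ctr, scl = standardize(covariates[c], "z")
        scalers[c] = (ctr, scl)
    fid = pd.Series(female_ids).astype(str)
    females = sorted(fid.unique())
    if len(females) < 2:
        raise ValueError("nest-fate model needs >= 2 females for the random intercept")
    g = fid.map({f: i for i, f in enumerate(females)}).to_numpy()
    nf, p = len(females), len(names)

    ss = np.random.SeedSequence(seed)
    chain_draws = []  # per chain: dict arrays
    for cs in ss.spawn(chains):
        rng = np.random.default_rng(cs)
        # non-centered parameterization: b = sigma * u, u ~ N(0, 1),
        # which mixes far better when the random effect is weakly identified
        beta = rng.normal(0, 0.1, p + 1)  # [intercept, betas]
        u = rng.normal(0, 0.1, nf)
        log_sig = np.log(0.5) + rng.normal(0, 0.1)
        s_beta, s_u, s_sig = 0.1, 0.5, 0.3

        def eta_of(beta, u, log_sig):
            return beta[0] + Z @ beta[1:] + np.exp(log_sig) * u[g]

        ll = _loglik_rows(eta_of(beta, u, log_sig), y).sum()
        keep = iterations - burn_in
        out = {"beta": np.empty((keep, p + 1)), "b": np.empty((keep, nf)),
               "sigma": np.empty(keep)}
        for it in range(iterations):
            adapting = adapt and it < burn_in
            # --- coefficient block
            prop = beta + rng.normal(0, s_beta, p + 1)
            ll_prop = _loglik_rows(eta_of(prop, u, log_sig), y).sum()
            lp = (ll_prop - ll) + ((beta**2 - prop**2).sum()) / (2 * prior_sd_beta**2)
            acc = np.log(rng.random()) < lp
            if acc:
                beta, ll = prop, ll_prop
            if adapting:
                s_beta *= np.exp(0.02 * ((1.0 if acc else 0.0) - 0.25))
            # --- standardized female intercepts, vectorized independent updates
            sig = np.exp(log_sig)
            up = u + rng.normal(0, s_u, nf)
            eta = eta_of(beta, u, log_sig)
            delta_rows = _loglik_rows(eta + sig * (up - u)[g], y) - _loglik_rows(eta, y)
            delta_f = np.bincount(g, weights=delta_rows, minlength=nf)
            delta_f += (u**2 - up**2) / 2.0
            acc_f = np.log(rng.random(nf)) < delta_f
            u = np.where(acc_f, up, u)
            if adapting:
                s_u *= np.exp(0.02 * (acc_f.mean() - 0.35))
            ll = _loglik_rows(eta_of(beta, u, log_sig), y).sum()
            # --- sigma_b on the log scale (half-Normal prior + Jacobian);
            # rescales every female intercept at once in this parameterization
            ls_prop = log_sig + rng.normal(0, s_sig)
            ll_prop = _loglik_rows(eta_of(beta, u, ls_prop), y).sum()
            lp = (ll_prop - ll
                  + (np.exp(2 * log_sig) - np.exp(2 * ls_prop)) / (2 * prior_sd_sigma**2)
                  + (ls_prop - log_sig))
            acc_s = np.log(rng.random()) < lp
            if acc_s:
                log_sig, ll = ls_prop, ll_prop
            if adapting:
                s_sig *= np.exp(0.02 * ((1.0 if acc_s else 0.0) - 0.35))
            if it >= burn_in:
                out["beta"][it - burn_in] = beta
                out["b"][it - burn_in] = np.exp(log_sig) * u
                out["sigma"][it - burn_in] = np.exp(log_sig)
        chain_draws.append(out)

    param_names = ["intercept", *names, "sigma_b"]
    per_param = {}
    for k, nm in enumerate(param_names[:-1]):
        per_param[nm] = np.stack([cd["beta"][:, k] for cd in chain_draws])
    per_param["sigma_b"] = np.stack([cd["sigma"] for cd in chain_draws])
    per_param["_b"] = np.stack([cd["b"] for cd in chain_draws])

    mean, lo, hi, pds, rhats = [], [], [], [], []
    for nm in param_names:
        d = per_param[nm]
        pooled = d.ravel()
        mean.append(pooled.mean())
        lo.append(np.percentile(pooled, 2.5))
        hi.append(np.percentile(pooled, 97.5))
        pds.append(probability_of_direction(pooled) if nm != "sigma_b" else 1.0)
        rhats.append(rhat(d))
    converged = bool(np.all(np.asarray(rhats) < 1.1))
    if not converged:
        warnings.warn("nest-fate MCMC did not converge: max split R-hat "
                      f"{max(rhats):.3f} >= 1.1")
    sig_pooled = per_param["sigma_b"].ravel()
    return PosteriorSummary(params=param_names, mean=np.array(mean),
                            ci_lower=np.array(lo), ci_upper=np.array(hi),
                            pd=np.array(pds), rhat=np.array(rhats),
                            sigma_b_mean=float(sig_pooled.mean()),
                            sigma_b2_mean=float((sig_pooled**2).mean()),
                            converged=converged, draws=per_param, scalers=scalers)


def marginal_effect(posterior: PosteriorSummary, covariates: pd.DataFrame,
                    female_ids, covariate: str = "n_clp_visited",
                    delta: float = 1.0, max_draws: int = 2000) -> float:
    """Average marginal effect of a ``delta`` original-scale step, in
    percentage points of success probability.

    Averages ``p(z + delta_std) - p(z)`` over posterior draws and observed
    rows, including each row's female intercept draw, with ``delta_std``
    the step converted to the standardized scale the model was fitted on.
    """
    names = [p for p in posterior.params if p not in ("intercept", "sigma_b")]
    k = names.index(covariate)
    _, scale = posterior.scalers[covariate][0], posterior.scalers[covariate][1]
    delta_std = delta / scale
    Z = np.column_stack([
        (covariates[c].to_numpy(float) - posterior.scalers[c][0]) / posterior.scalers[c][1]
        for c in names])
    fid = pd.Series(female_ids).astype(str)
    females = sorted(fid.unique())
    g = fid.map({f: i for i, f in enumerate(females)}).to_numpy()

    beta_draws = np.concatenate([posterior.draws[nm].reshape(-1, 1)
                                 for nm in ["intercept", *names]], axis=1)
    b_draws = posterior.draws["_b"].reshape(-1, posterior.draws["_b"].shape[-1])
    if len(beta_draws) > max_draws:
        idx = np.linspace(0, len(beta_draws) - 1, max_draws).astype(int)
        beta_draws, b_draws = beta_draws[idx], b_draws[idx]
    eta = beta_draws[:, 0:1] + beta_draws[:, 1:] @ Z.T + b_draws[:, g]
    eta2 = eta + beta_draws[:, 1 + k][:, None] * delta_std
    return float((expit(eta2) - expit(eta)).mean() * 100.0)


# ----------------------------------------------------------------- RSF GLMM

class SeparationError(RuntimeError):
    pass


@dataclass
class RSFFit:
    covariates: list[str]
    beta: np.ndarray  # [intercept, covariates...] on the 2-SD scale
    se: np.ndarray
    sigma_b2: float
    n_used: int
    n_available: int
    dropped: list[str]
    scalers: dict
    loglik: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "se": self.se},
                            index=["intercept", *self.covariates])


def _rsf_negll(theta, X, y, g, nf, nodes, wts):
    """Marginal negative log-likelihood, adaptive Gauss-Hermite per group."""
    beta, log_sig = theta[:-1], theta[-1]
    sig = max(np.exp(log_sig), 1e-8)  # floor keeps the boundary fit finite
    eta0 = X @ beta
    # inner Newton for the per-group posterior mode of b
    b = np.zeros(nf)
    for _ in range(25):
        p = expit(eta0 + b[g])
        grad = np.bincount(g, weights=y - p, minlength=nf) - b / sig**2
        hess = -np.bincount(g, weights=p * (1 - p), minlength=nf) - 1 / sig**2
        step = grad / hess
        b -= np.clip(step, -5, 5)
        if np.max(np.abs(step)) < 1e-9:
            break
    p = expit(eta0 + b[g])
    tau = 1.0 / np.sqrt(np.bincount(g, weights=p * (1 - p), minlength=nf) + 1 / sig**2)
    # AGQ: integrate exp(h(b)) phi-free form with nodes centered at the mode
    ll = 0.0
    acc = np.zeros(nf)
    log_terms = np.empty((len(nodes), nf))
    for j, (x, w) in enumerate(zip(nodes, wts)):
        bj = b + tau * x
        lr = _loglik_rows(eta0 + bj[g], y)
        lg = np.bincount(g, weights=lr, minlength=nf)
        log_phi = -0.5 * (bj / sig) ** 2 - np.log(sig) - 0.5 * np.log(2 * np.pi)
        # hermegauss weights contain exp(-x^2/2) factor; add it back
        log_terms[j] = np.log(w) + 0.5 * x**2 + lg + log_phi + np.log(tau)
    m = log_terms.max(axis=0)
    ll = float((m + np.log(np.exp(log_terms - m).sum(axis=0))).sum())
    return -ll


def fit_rsf(table: pd.DataFrame, covariates: list[str], female_ids,
            response: str = "used", r_max: float = 0.60, n_agq: int = 15,
            rescale: bool = True) -> RSFFit:
    """Maximum-likelihood used/available logistic GLMM with a per-female
    random intercept.

    Applies the Pearson collinearity screen, then the 2-SD rescale, then
    fits by adaptive Gauss-Hermite quadrature (``n_agq`` nodes).  Standard
    errors come from the numerical Hessian at the optimum.  Complete
    separation raises naming the covariate; a boundary random-effect
    variance is reported as 0 with a warning.
    """
    y = table[response].to_numpy(int)
    kept = screen_collinearity(table[covariates], r_max=r_max)
    dropped = [c for c in covariates if c not in kept]
    scalers = {}
    cols = []
    for c in kept:
        if rescale:
            z, ctr, scl = standardize(table[c], "2sd")
        else:
            z, ctr, scl = table[c].to_numpy(float), 0.0, 1.0
        scalers[c] = (ctr, scl)
        cols.append(z)
    X = np.column_stack([np.ones(len(y)), *cols])
    fid = pd.Series(female_ids).astype(str)
    females = sorted(fid.unique())
    g = fid.map({f: i for i, f in enumerate(females)}).to_numpy()
    nf = len(females)
    nodes, wts = hermegauss(n_agq)

    theta0 = np.zeros(X.shape[1] + 1)
    theta0[-1] = np.log(0.5)
    res = minimize(_rsf_negll, theta0, args=(X, y, g, nf, nodes, wts),
                   method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    theta = res.x
    beta, sig = theta[:-1], np.exp(theta[-1])
    big = np.flatnonzero(np.abs(beta[1:]) > 15)
    if big.size:
        raise SeparationError(f"complete separation suspected for {kept[big[0]]!r}")
    if sig < 1e-3:
        warnings.warn("random-intercept variance at the boundary; reported as 0")
        sig = 0.0

    # numerical Hessian over beta (log-sigma profiled at the optimum)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    npar = len(theta)
    H = np.zeros((npar, npar))
    f0 = _rsf_negll(theta, X, y, g, nf, nodes, wts)
    for i in range(npar):
        for j in range(i, npar):
            ti = np.zeros(npar); ti[i] = h[i]
            tj = np.zeros(npar); tj[j] = h[j]
            fpp = _rsf_negll(theta + ti + tj, X, y, g, nf, nodes, wts)
            fpm = _rsf_negll(theta + ti - tj, X, y, g, nf, nodes, wts)
            fmp = _rsf_negll(theta - ti + tj, X, y, g, nf, nodes, wts)
            fmm = _rsf_negll(theta - ti - tj, X, y, g, nf, nodes, wts)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(npar - 1, np.nan)

    return RSFFit(covariates=kept, beta=beta, se=se, sigma_b2=float(sig**2),
                  n_used=int(y.sum()), n_available=int((1 - y).sum()),
                  dropped=dropped, scalers=scalers, loglik=float(-f0))
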