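"""Dynamic Brownian bridge movement model (dBBMM) incubation ranges.

The utilization distribution (UD) of a track is a time-integrated mixture
of Brownian-bridge densities between consecutive fixes.  The Brownian
motion variance sigma2_m (m^2 per unit time) is estimated by leave-one-out
likelihood of the odd-indexed interior fixes given their temporal
neighbours, in a sliding window (default 7 fixes) that may contain one
breakpoint splitting it into two variance regimes when BIC prefers it; the
breakpoint must leave at least ``margin`` fixes (default 3) on each side.
Each fix's sigma2_m is the mean over all windows covering it.  A fixed
isotropic location error (default 20 m) enters every bridge variance.

With the variance held constant the construction reduces to the plain
Brownian bridge movement model, which serves as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class UDGrid:
    """A normalized utilization distribution on a square-cell grid."""

    density: np.ndarray  # rows = y (row 0 south), cols = x; sums to 1
    origin: tuple[float, float]  # lower-left corner
    cell_size: float

    def cell_centers(self):
        ny, nx = self.density.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys


def _bridge_obs(times: np.ndarray, xy: np.ndarray, idx: np.ndarray):
    """Leave-one-out geometry for interior fixes ``idx``: the observed fix
    against the bridge between its temporal neighbours."""
    t0, t1, t2 = times[idx - 1], times[idx], times[idx + 1]
    T = t2 - t0
    alpha = (t1 - t0) / T
    mu = xy[idx - 1] + alpha[:, None] * (xy[idx + 1] - xy[idx - 1])
    d2 = ((xy[idx] - mu) ** 2).sum(axis=1)
    return T, alpha, d2


def _negll(sigma2: float, T, alpha, d2, error_m: float) -> float:
    # LOO variance: bridge diffusion + endpoint errors propagated to the
    # bridge mean + the left-out fix's own location error
    v = sigma2 * T * alpha * (1 - alpha) + error_m**2 * ((1 - alpha) ** 2 + alpha**2 + 1.0)
    return float(np.sum(np.log(2 * np.pi * v) + d2 / (2 * v)))


def _fit_sigma2(T, alpha, d2, error_m: float, upper: float) -> tuple[float, float]:
    res = minimize_scalar(_negll, bounds=(0.0, upper), args=(T, alpha, d2, error_m),
                          method="bounded", options={"xatol": max(upper * 1e-6, 1e-9)})
    return float(res.x), float(res.fun)


def estimate_motion_variance(times: np.ndarray, xy: np.ndarray, window: int = 7,
                             margin: int = 3, error_m: float = 20.0) -> np.ndarray:
    """Per-fix Brownian motion variance series (m^2 per unit time).

    ``times`` are numeric (any consistent unit; the pipeline uses seconds).
    Falls back to a single global estimate with a warning when the track is
    shorter than ``window`` fixes.
    """
    times = np.asarray(times, float)
    xy = np.asarray(xy, float)
    n = len(times)
    if n < 3:
        raise ValueError("need at least 3 fixes to estimate motion variance")
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    interior = np.arange(1, n - 1)
    loo = interior[::2]  # odd-indexed fixes (1, 3, 5, ...)
    scale = max(((xy.max(0) - xy.min(0)) ** 2).sum(), error_m**2)
    upper = 100.0 * scale / max(times[-1] - times[0], 1e-9)

    if n < window:
        warnings.warn("track shorter than the estimation window; using one global sigma2_m")
        T, alpha, d2 = _bridge_obs(times, xy, loo)
        s2, _ = _fit_sigma2(T, alpha, d2, error_m, upper)
        return np.full(n, s2)

    acc = np.zeros(n)
    cnt = np.zeros(n)
    for start in range(0, n - window + 1):
        fidx = np.arange(start, start + window)
        w_loo = loo[(loo > start) & (loo < start + window - 1)]
        if len(w_loo) == 0:
            continue
        T, alpha, d2 = _bridge_obs(times, xy, w_loo)
        s2_all, nll_all = _fit_sigma2(T, alpha, d2, error_m, upper)
        m = len(w_loo)
        best = (nll_all * 2 + 1 * np.log(max(m, 1)), None, s2_all, s2_all)
        # one optional breakpoint, honoring the margin on both sides
        for brk in range(start + margin, start + window - margin + 1):
            left = w_loo[w_loo < brk]
            right = w_loo[w_loo >= brk]
            if len(left) == 0 or len(right) == 0:
                continue
            sL, nL = _fit_sigma2(*_bridge_obs(times, xy, left), error_m, upper)
            sR, nR = _fit_sigma2(*_bridge_obs(times, xy, right), error_m, upper)
            bic = (nL + nR) * 2 + 2 * np.log(m)
            if bic < best[0]:
                best = (bic, brk, sL, sR)
        _, brk, sL, sR = best
        if brk is None:
            acc[fidx] += sL
        else:
            acc[start:brk] += sL
            acc[brk:start + window] += sR
        cnt[fidx] += 1

    out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    if np.isnan(out).any():  # edge fixes never interior to any window
        good = ~np.isnan(out)
        out = np.interp(np.arange(n), np.flatnonzero(good), out[good])
    return out


def build_ud(times: np.ndarray, xy: np.ndarray, sigma2: np.ndarray,
             grid_resolution: float = 30.0, error_m: float = 20.0,
             n_time_steps: int = 10, pad_sd: float = 5.0) -> UDGrid:
    """Discretized UD: integrate the bridge density over each inter-fix leg.

    ``sigma2`` is per fix; each bridge uses the mean of its endpoint values.
    Bridge variance at fractional time a is
    ``sigma2*T*a*(1-a) + error^2*((1-a)^2 + a^2)``.  The grid auto-expands
    until >= 99.9% of the analytic mass falls inside before normalization.
    """
    times = np.asarray(times, float)
    xy = np.asarray(xy, float)
    sigma2 = np.asarray(sigma2, float)
    if len(times) == 1:
        xy = np.vstack([xy, xy])
        times = np.array([times[0], times[0] + 1.0])
        sigma2 = np.array([sigma2[0], sigma2[0]])
    s2b = 0.5 * (sigma2[:-1] + sigma2[1:])
    T = np.diff(times)
    vmax = np.nanmax(s2b * T) * 0.25 + error_m**2

    pad = pad_sd * np.sqrt(vmax)
    for _ in range(8):
        x0 = np.floor((xy[:, 0].min() - pad) / grid_resolution) * grid_resolution
        y0 = np.floor((xy[:, 1].min() - pad) / grid_resolution) * grid_resolution
        nx = int(np.ceil((xy[:, 0].max() + pad - x0) / grid_resolution))
        ny = int(np.ceil((xy[:, 1].max() + pad - y0) / grid_resolution))
        xs = x0 + (np.arange(nx) + 0.5) * grid_resolution
        ys = y0 + (np.arange(ny) + 0.5) * grid_resolution
        dens = np.zeros((ny, nx))
        fracs = (np.arange(n_time_steps) + 0.5) / n_time_steps
        for i in range(len(T)):
            a0, b0 = xy[i], xy[i + 1]
            stationary = s2b[i] * T[i] == 0 and np.array_equal(a0, b0)
            for a in fracs:
                mu = (1 - a) * a0 + a * b0
                if stationary:
                    # a motionless leg is just the fix seen through the
                    # location error: one isotropic Gaussian of sd error_m
                    v = error_m**2
                else:
                    v = s2b[i] * T[i] * a * (1 - a) + error_m**2 * ((1 - a) ** 2 + a**2)
                w = T[i] / n_time_steps
                r = 8.5 * np.sqrt(v)  # truncation below double-precision relevance
                jx = slice(*np.searchsorted(xs, [mu[0] - r, mu[0] + r]))
                jy = slice(*np.searchsorted(ys, [mu[1] - r, mu[1] + r]))
                gx = np.exp(-((xs[jx] - mu[0]) ** 2) / (2 * v))
                gy = np.exp(-((ys[jy] - mu[1]) ** 2) / (2 * v))
                dens[jy, jx] += (w / (2 * np.pi * v)) * np.outer(gy, gx)
        # the grid is large enough when essentially no mass reaches its rim
        border = (dens[0, :].sum() + dens[-1, :].sum()
                  + dens[:, 0].sum() + dens[:, -1].sum())
        if border <= 1e-4 * dens.sum():
            break
        warnings.warn("UD grid too small to hold the distribution tails; expanding")
        pad *= 1.6
    dens /= dens.sum()
    return UDGrid(dens, (x0, y0), grid_resolution)


def contour(ud: UDGrid, level: float = 0.95) -> np.ndarray:
    """Smallest cell set whose cumulative density reaches ``level``.

    Cells are sorted by density (descending) and accumulated until the mass
    is >= level; with ``level=1`` every positive-density cell is included.
    """
    flat = ud.density.ravel()
    if level >= 1.0:
        return (ud.density > 0).copy()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12)) + 1
    mask = np.zeros(flat.size, bool)
    sel = order[:k]
    mask[sel[flat[sel] > 0]] = True
    return mask.reshape(ud.density.shape)


def sample_available(mask: np.ndarray, ud: UDGrid, n: int = 500,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform points over the masked area: cell chosen with equal area
    weight, position uniform within the cell.  Deterministic under ``rng``."""
    if not mask.any():
        raise ValueError("cannot sample from an empty contour mask")
    rng = rng or np.random.default_rng()
    cells = np.flatnonzero(mask.ravel())
    pick = rng.choice(cells, size=n, replace=True)
    iy, ix = np.unravel_index(pick, mask.shape)
    u = rng.random((n, 2))
    x = ud.origin[0] + (ix + u[:, 0]) * ud.cell_size
    y = ud.origin[1] + (iy + u[:, 1]) * ud.cell_size
    return np.column_stack([x, y])


def dbbmm_range(timestamps, xy, window: int = 7, margin: int = 3,
                error_m: float = 20.0, grid_resolution: float = 30.0,
                level: float = 0.95) -> tuple[UDGrid, np.ndarray, np.ndarray]:
    """Convenience wrapper: motion variance -> UD -> contour mask.

    ``timestamps`` may be datetimes (converted to seconds) or numbers.
    Returns (ud, mask, sigma2 series).
    """
    t = np.asarray(timestamps)
    if np.issubdtype(t.dtype, np.datetime64) or t.dtype == object:
        t = (np.asarray(t, "datetime64[s]") - np.asarray(t, "datetime64[s]")[0]) / np.timedelta64(1, "s")
    t = np.asarray(t, float)
    s2 = estimate_motion_variance(t, xy, window=window, margin=margin, error_m=error_m)
    ud = build_ud(t, xy, s2, grid_resolution=grid_resolution, error_m=error_m)
    return ud, contour(ud, level), s2
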