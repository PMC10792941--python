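"""Synthetic landscapes, trajectories, and nest fates with known ground truth.

The generator emulates the data-collecting conditions of a GPS-telemetry
nesting study on wild turkeys: transmitters record one nightly fix at
23:58:58 and hourly fixes from 05:00 to 20:00 local standard time.  Each
simulated female lays for ``laying_days`` days — visiting her nest briefly
once a day, foraging in a handful of fixed patches, and roosting off the
nest at night — then incubates for ``incubation_days`` days, sitting on the
nest except for a Poisson number of daily recess excursions.  Laying-night
roost sites scatter around a roost center (night-to-night sd
``roost_jitter_m``), as birds rarely perch at an identical point twice.  Each recess
targets one of her laying patches with probability ``p_revisit``, otherwise
a fresh random location 60–900 m from the nest.  Isotropic Gaussian GPS
noise is added to every fix.

Everything downstream (segmentation, clustering, recursion counts, the
fate and selection models) can therefore be scored against exact truth.
The movement model is deliberately minimal: no correlated random walk, no
habitat-dependent step selection beyond recess targeting, no weather.

Geometry constraints the generator enforces (documented as generator
constraints, not biology): recess targets lie 60–900 m from the nest so the
27.5-m recess rule separates classes cleanly at realistic noise; laying
patches are mutually >= 500 m apart and >= 300 m from the nest so each
forms its own clustered laying patch; the roost is 200–300 m from the nest.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .gps import Trajectory
from .landscape import DEFAULT_LEGEND, LandcoverRaster

HOURLY_HOURS = list(range(5, 21))  # 05:00 .. 20:00 inclusive -> 16 fixes
NIGHTLY = dt.time(23, 58, 58)
RECESS_MIN_M = 60.0
RECESS_MAX_M = 900.0

# equirectangular local projection for the geographic code path
_LAT0, _LON0 = 32.5, -83.0
_M_PER_DEG = np.pi / 180.0 * 6_371_000.0


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic population.

    Defaults emulate the fix schedule and covariate structure of the field
    study the pipeline is designed for: 12-day laying, 28-day incubation,
    mean proportion of recesses returning to laying patches 0.57, female
    random-intercept spread ~1.2 on the logit scale, and a positive effect
    of patches-visited on nest fate (0.19 per SD).
    """

    n_females: int = 20
    laying_days: int = 12
    incubation_days: int = 28
    n_patches: int = 4
    p_revisit: float = 0.57
    recesses_per_day: float = 2.0
    gps_noise_sd: float = 10.0
    fate_intercept: float = 0.0
    fate_beta_prop: float = 0.0
    fate_beta_nclp: float = 0.19
    random_intercept_sd: float = 1.2
    rsf_betas: dict = field(default_factory=lambda: {
        "dist_nest": -2.04, "dist_hardwood": -0.27, "dist_water": -0.48,
        "dist_mixed": -0.10, "dist_road": -0.39, "dist_shrub": -0.16,
        "dist_open": 0.27, "dist_pine": 0.06})
    attempts_per_female: int = 1
    patch_spread_m: float = 25.0
    roost_jitter_m: float = 75.0  # night-to-night spread of roost sites
    coordinate_mode: str = "projected"
    start_date: dt.date = dt.date(2020, 4, 1)
    seed: int = 20200401

    def __post_init__(self) -> None:
        for name in ("n_females", "laying_days", "incubation_days", "n_patches",
                     "attempts_per_female"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.p_revisit <= 1.0:
            raise ConfigError("p_revisit must lie in [0, 1]")
        if self.gps_noise_sd < 0:
            raise ConfigError("gps_noise_sd must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth for one simulated nesting attempt."""

    female_id: str
    attempt_id: str
    attempt_index: int
    true_nest_xy: tuple[float, float]
    true_laying_onset: dt.date
    true_incubation_onset: dt.date
    true_incubation_end: dt.date
    patch_centers: list[tuple[float, float]]
    roost_xy: tuple[float, float]
    labels: list[str]  # per fix: laying-forage | nest-visit | roost | on-nest | recess
    recess_target: list  # per fix: patch index (int) | "fresh" | None
    fate: str = "unknown"

    @property
    def true_proportion_to_clp(self) -> float:
        n_rec = sum(lb == "recess" for lb in self.labels)
        n_patch = sum(isinstance(t, int) for t in self.recess_target)
        return n_patch / n_rec if n_rec else 0.0

    @property
    def true_n_clp_visited(self) -> int:
        return len({t for t in self.recess_target if isinstance(t, int)})

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("true_laying_onset", "true_incubation_onset", "true_incubation_end"):
            d[k] = d[k].isoformat()
        return json.dumps(d)


def generate_landscape(extent=(5100.0, 5100.0), resolution: float = 30.0,
                       class_mix=None, n_roads: int = 2, seed: int = 0,
                       origin=(0.0, 0.0)) -> tuple[LandcoverRaster, list]:
    """Blob-textured six-class landcover raster plus road polylines.

    Classes come from a smoothed Gaussian random field thresholded at the
    cumulative class-mix quantiles, giving contiguous patches at Cropland-
    Data-Layer-like 30-m granularity with class proportions matching
    ``class_mix``.  Roads are independent polylines crossing the extent.
    """
    if extent[0] <= 0 or extent[1] <= 0 or resolution <= 0:
        raise ConfigError("extent and resolution must be positive")
    nx, ny = int(round(extent[0] / resolution)), int(round(extent[1] / resolution))
    if abs(nx * resolution - extent[0]) > 1e-6 or abs(ny * resolution - extent[1]) > 1e-6:
        raise ConfigError("extent must be divisible by resolution")
    mix = np.full(6, 1 / 6) if class_mix is None else np.asarray(class_mix, float)
    if mix.min() < 0 or mix.sum() <= 0:
        raise ConfigError("class_mix weights must be non-negative and not all zero")
    mix = mix / mix.sum()

    rng = np.random.default_rng(seed)
    fld = gaussian_filter(rng.standard_normal((ny, nx)), sigma=3.0, mode="wrap")
    ranks = fld.ravel().argsort().argsort().reshape(fld.shape) / max(fld.size - 1, 1)
    edges = np.cumsum(mix)
    # right-sided search skips zero-width classes; ranks clamp to the
    # positive-weight class range so rank 1.0 lands in the last real class
    pos = np.flatnonzero(mix > 0)
    grid = np.clip(np.searchsorted(edges, ranks, side="right"), pos[0], pos[-1]) + 1
    raster = LandcoverRaster(grid, origin, resolution, dict(DEFAULT_LEGEND))

    roads = []
    x0, y0 = origin
    for _ in range(n_roads):
        horizontal = rng.random() < 0.5
        c = rng.uniform(0.2, 0.8)
        ts = np.linspace(0.0, 1.0, 9)
        wig = rng.normal(0.0, 0.03, size=ts.size).cumsum()
        a = ts
        b = np.clip(c + wig, 0.05, 0.95)
        xs, ys = (a, b) if horizontal else (b, a)
        roads.append(shapely.LineString(
            np.column_stack([x0 + xs * extent[0], y0 + ys * extent[1]])))
    return raster, roads


def _schedule(start: dt.date, n_days: int) -> list[dt.datetime]:
    out = []
    for d in range(n_days):
        day = start + dt.timedelta(days=d)
        out.extend(dt.datetime.combine(day, dt.time(h, 0, 0)) for h in HOURLY_HOURS)
        out.append(dt.datetime.combine(day, NIGHTLY))
    return out


def _place_points(rng, nest, n, r_lo, r_hi, min_sep, others=(), max_tries=2000):
    pts = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(r_lo, r_hi)
        p = nest + r * np.array([np.cos(ang), np.sin(ang)])
        if all(np.hypot(*(p - q)) >= min_sep for q in [*pts, *others]):
            pts.append(p)
    if len(pts) < n:
        raise ConfigError("could not place patch centers; enlarge extent or relax spacing")
    return pts


def generate_attempt(cfg: SimConfig, landscape: LandcoverRaster, female_id: str,
                     rng: np.random.Generator, attempt_index: int = 1,
                     start_date: dt.date | None = None) -> tuple[Trajectory, TruthRecord]:
    """One nesting attempt: laying + incubation fixes with per-fix truth labels."""
    x0, y0 = landscape.origin
    ex = landscape.shape[1] * landscape.cell_size
    ey = landscape.shape[0] * landscape.cell_size
    margin = 2 * RECESS_MAX_M
    if ex <= 2 * margin or ey <= 2 * margin:
        raise ConfigError(f"landscape extent must exceed {2 * margin:.0f} m per axis")
    nest = np.array([rng.uniform(x0 + margin, x0 + ex - margin),
                     rng.uniform(y0 + margin, y0 + ey - margin)])
    roost = _place_points(rng, nest, 1, 200.0, 300.0, 0.0)[0]
    patches = _place_points(rng, nest, cfg.n_patches, 300.0, RECESS_MAX_M - 50.0,
                            500.0, others=[roost])

    start = start_date or cfg.start_date
    lay_start = start
    inc_start = start + dt.timedelta(days=cfg.laying_days)
    inc_end = inc_start + dt.timedelta(days=cfg.incubation_days)

    times, pos, labels, targets = [], [], [], []

    for d in range(cfg.laying_days):
        day = lay_start + dt.timedelta(days=d)
        visit_hour = HOURLY_HOURS[rng.integers(len(HOURLY_HOURS))]
        # two foraging patches per day, cycling so every patch accrues fixes
        day_patches = [patches[(2 * d) % cfg.n_patches], patches[(2 * d + 1) % cfg.n_patches]]
        for h in HOURLY_HOURS:
            times.append(dt.datetime.combine(day, dt.time(h, 0, 0)))
            if h == visit_hour:
                pos.append(nest.copy())
                labels.append("nest-visit")
            else:
                ctr = day_patches[int(h > 12)]
                pos.append(ctr + rng.normal(0.0, cfg.patch_spread_m, 2))
                labels.append("laying-forage")
            targets.append(None)
        times.append(dt.datetime.combine(day, NIGHTLY))
        pos.append(roost + rng.normal(0.0, cfg.roost_jitter_m, 2))
        labels.append("roost")
        targets.append(None)

    for d in range(cfg.incubation_days):
        day = inc_start + dt.timedelta(days=d)
        n_rec = min(int(rng.poisson(cfg.recesses_per_day)), len(HOURLY_HOURS))
        rec_hours = set(rng.choice(HOURLY_HOURS, size=n_rec, replace=False)) if n_rec else set()
        for h in HOURLY_HOURS:
            times.append(dt.datetime.combine(day, dt.time(h, 0, 0)))
            if h in rec_hours:
                if rng.random() < cfg.p_revisit:
                    k = int(rng.integers(cfg.n_patches))
                    ang = rng.uniform(0, 2 * np.pi)
                    r = 20.0 * np.sqrt(rng.random())
                    pos.append(patches[k] + r * np.array([np.cos(ang), np.sin(ang)]))
                    targets.append(k)
                else:
                    while True:
                        ang = rng.uniform(0, 2 * np.pi)
                        r = rng.uniform(RECESS_MIN_M, RECESS_MAX_M)
                        p = nest + r * np.array([np.cos(ang), np.sin(ang)])
                        if all(np.hypot(*(p - q)) >= 100.0 for q in [*patches, roost]):
                            break
                    pos.append(p)
                    targets.append("fresh")
                labels.append("recess")
            else:
                pos.append(nest.copy())
                labels.append("on-nest")
                targets.append(None)
        times.append(dt.datetime.combine(day, NIGHTLY))
        pos.append(nest.copy())
        labels.append("on-nest")
        targets.append(None)

    xy = np.array(pos) + rng.normal(0.0, cfg.gps_noise_sd, (len(pos), 2))
    dop = np.minimum(rng.lognormal(0.6, 0.55, len(pos)), 25.0)
    fixes = pd.DataFrame({"timestamp": pd.to_datetime(times), "x": xy[:, 0],
                          "y": xy[:, 1], "dop": dop})
    traj = Trajectory(female_id, fixes, mode="projected")
    truth = TruthRecord(
        female_id=female_id, attempt_id=f"{female_id}-{attempt_index}",
        attempt_index=attempt_index, true_nest_xy=(float(nest[0]), float(nest[1])),
        true_laying_onset=lay_start, true_incubation_onset=inc_start,
        true_incubation_end=inc_end,
        patch_centers=[(float(p[0]), float(p[1])) for p in patches],
        roost_xy=(float(roost[0]), float(roost[1])), labels=labels,
        recess_target=targets)
    if cfg.coordinate_mode == "geographic":
        traj = to_geographic(traj)
    return traj, truth


def to_geographic(traj: Trajectory) -> Trajectory:
    """Project planar meters to lon/lat with a fixed equirectangular projection
    centered at (32.5 N, 83 W), so the haversine code path can be exercised."""
    fixes = traj.fixes.copy()
    fixes["y"], fixes["x"] = _LAT0 + fixes["y"] / _M_PER_DEG, \
        _LON0 + fixes["x"] / (_M_PER_DEG * np.cos(np.radians(_LAT0)))
    return Trajectory(traj.female_id, fixes, mode="geographic")


def planar_to_lonlat(xy: np.ndarray) -> np.ndarray:
    xy = np.atleast_2d(np.asarray(xy, float))
    return np.column_stack([_LON0 + xy[:, 0] / (_M_PER_DEG * np.cos(np.radians(_LAT0))),
                            _LAT0 + xy[:, 1] / _M_PER_DEG])


def simulate_fates(truth_covariates: pd.DataFrame, cfg: SimConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Draw nest fates from the generative logistic model.

    ``truth_covariates`` needs columns female_id, proportion, n_clp.  Both
    covariates are standardized (sample sd) within the simulated population;
    fate_i ~ Bernoulli(logit^-1(a + b1 z1 + b2 z2 + b_female)) with the
    female intercept shared across a female's attempts.
    """
    df = truth_covariates.copy()
    if not np.isfinite(df[["proportion", "n_clp"]].to_numpy(float)).all():
        raise ValueError("non-finite fate covariates")

    def z(x):
        x = np.asarray(x, float)
        s = x.std(ddof=1) if len(x) > 1 else 0.0
        return (x - x.mean()) / s if np.isfinite(s) and s > 0 else np.zeros_like(x)

    z1, z2 = z(df["proportion"]), z(df["n_clp"])
    females = df["female_id"].unique()
    b = dict(zip(females, rng.normal(0.0, cfg.random_intercept_sd, len(females))))
    eta = (cfg.fate_intercept + cfg.fate_beta_prop * z1 + cfg.fate_beta_nclp * z2
           + df["female_id"].map(b).to_numpy(float))
    p = expit(eta)
    df["p_success"] = p
    df["fate"] = np.where(rng.random(len(df)) < p, "success", "fail")
    return df


def generate_population(cfg: SimConfig, landscape: LandcoverRaster | None = None,
                        roads=None):
    """Full synthetic study: landscape, per-attempt trajectories + truth, fates.

    Returns (landscape, roads, trajectories, truths).  Determined entirely
    by ``cfg`` (including ``cfg.seed``).
    """
    ss = np.random.SeedSequence(cfg.seed)
    land_seed, *att_seeds = ss.spawn(cfg.n_females * cfg.attempts_per_female + 1)
    if landscape is None:
        landscape, roads = generate_landscape(seed=land_seed.generate_state(1)[0] % 2**31)

    trajectories, truths = [], []
    k = 0
    for f in range(cfg.n_females):
        fid = f"F{f + 1:03d}"
        parts, start = [], cfg.start_date
        for a in range(cfg.attempts_per_female):
            rng = np.random.default_rng(att_seeds[k]); k += 1
            traj, truth = generate_attempt(cfg, landscape, fid, rng,
                                           attempt_index=a + 1, start_date=start)
            parts.append(traj.fixes)
            truths.append(truth)
            start = truth.true_incubation_end + dt.timedelta(days=5)
        trajectories.append(Trajectory(fid, pd.concat(parts, ignore_index=True),
                                       mode=cfg.coordinate_mode))

    cov = pd.DataFrame({
        "female_id": [t.female_id for t in truths],
        "attempt_id": [t.attempt_id for t in truths],
        "proportion": [t.true_proportion_to_clp for t in truths],
        "n_clp": [t.true_n_clp_visited for t in truths]})
    fate_rng = np.random.default_rng(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    fates = simulate_fates(cov, cfg, fate_rng)
    for t, fate in zip(truths, fates["fate"]):
        t.fate = fate
    return landscape, roads, trajectories, fates, truths


def simulate_selection_points(surfaces: dict, raster: LandcoverRaster, betas: dict,
                              n_females: int = 30, points_per_female: int = 250,
                              base_rate: float = 0.15, random_intercept_sd: float = 0.0,
                              seed: int = 0) -> pd.DataFrame:
    """Used/available tables with known selection strength, for scoring the
    resource-selection model.

    For each female, candidate points are scattered uniformly over the
    raster and labelled used ~ Bernoulli(logit^-1(a0 + b_f + sum_c beta_c
    z_c)) with z_c the 2-SD-standardized distance covariate — i.e. exactly
    the generative process the used/available GLMM assumes.  ``betas`` maps
    covariate names (``dist_water``, ...) to coefficients on the 2-SD scale.
    """
    from .landscape import extract_covariates

    rng = np.random.default_rng(seed)
    ny, nx = raster.shape
    ex, ey = nx * raster.cell_size, ny * raster.cell_size
    rows = []
    n_tot = n_females * points_per_female
    pts = np.column_stack([
        raster.origin[0] + rng.uniform(0, ex, n_tot),
        raster.origin[1] + rng.uniform(0, ey, n_tot)])
    cov = extract_covariates(pts, raster, surfaces)
    cov = cov.drop(columns="error")
    z = pd.DataFrame({c: (cov[c] - cov[c].mean()) / (2 * cov[c].std(ddof=1))
                      for c in cov.columns})
    eta = np.full(n_tot, np.log(base_rate / (1 - base_rate)))
    for c, b in betas.items():
        if c in z:
            eta = eta + b * z[c].to_numpy()
    fid = np.repeat([f"F{i + 1:03d}" for i in range(n_females)], points_per_female)
    b_f = dict(zip(np.unique(fid), rng.normal(0, random_intercept_sd, n_females)))
    eta = eta + pd.Series(fid).map(b_f).to_numpy()
    used = (rng.random(n_tot) < expit(eta)).astype(int)
    out = cov.copy()
    out.insert(0, "used", used)
    out.insert(0, "female_id", fid)
    return out


def write_truths(truths: list[TruthRecord], path) -> None:
    Path(path).write_text("\n".join(t.to_json() for t in truths) + "\n")


def read_truths(path) -> list[TruthRecord]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        for k in ("true_laying_onset", "true_incubation_onset", "true_incubation_end"):
            d[k] = dt.date.fromisoformat(d[k])
        d["true_nest_xy"] = tuple(d["true_nest_xy"])
        d["roost_xy"] = tuple(d["roost_xy"])
        d["patch_centers"] = [tuple(p) for p in d["patch_centers"]]
        out.append(TruthRecord(**d))
    return out
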