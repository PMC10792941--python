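"""End-to-end orchestration of the prospecting analysis.

``run_pipeline`` executes simulate -> segment -> prospect -> range -> rsf ->
fate on a synthetic population and writes deterministic summary tables plus
a machine-readable run manifest.  Every stage is also callable on its own
(the functions below), which is how the numbered scripts under
``analysis/`` and the test suite drive the package.

Determinism contract: a rerun with an identical config (including seeds)
produces byte-identical summary tables; every output embeds the config
hash.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gps, home_range, landscape, models, phenology, prospecting
from .synthetic import SimConfig, generate_population, write_truths

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters in one flat, serializable record."""

    sim: SimConfig = field(default_factory=SimConfig)
    dop_max: float = 7.0
    visit_radius_m: float = 20.0
    lookback_days: int = 20
    recess_threshold_m: float = 27.5
    linkage_radius_m: float = 150.0
    buffer_radius_m: float = 45.0
    min_incubation_days: int = 3
    dbbmm_window: int = 7
    dbbmm_margin: int = 3
    dbbmm_error_m: float = 20.0
    grid_resolution_m: float = 30.0
    n_available: int = 500
    r_max: float = 0.60
    mcmc_chains: int = 4
    mcmc_iterations: int = 8000
    mcmc_burn_in: int = 1000
    seed: int = 7

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["start_date"] = d["sim"]["start_date"].isoformat()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def segment_attempts(trajectories, truths=None, cfg: PipelineConfig | None = None):
    """DOP-filter each trajectory and derive nesting attempts.

    Returns (attempts kept, attempts removed, per-female cleaned
    trajectories, stage counts).  Fates are attached from the simulated
    truth records when provided.
    """
    cfg = cfg or PipelineConfig()
    fate_by_attempt = {t.attempt_id: t.fate for t in truths} if truths else {}
    kept_all, removed_all, cleaned = [], [], {}
    counts = {"fixes_in": 0, "fixes_kept": 0}
    for traj in trajectories:
        counts["fixes_in"] += len(traj)
        tr = gps.filter_dop(traj, cfg.dop_max)
        counts["fixes_kept"] += len(tr)
        cleaned[tr.female_id] = tr
        attempts = phenology.derive_attempts(
            tr, lookback_days=cfg.lookback_days, visit_radius_m=cfg.visit_radius_m,
            on_nest_radius_m=cfg.recess_threshold_m)
        kept, removed = phenology.filter_attempts(attempts, cfg.min_incubation_days)
        kept_all.extend(kept)
        removed_all.extend(removed)
    # attempt indices are renumbered among kept attempts so that initial vs
    # renest ordering refers to attempts long enough to analyze
    kept_all.sort(key=lambda a: (a.female_id, a.incubation_onset))
    idx = {}
    for a in kept_all:
        idx[a.female_id] = idx.get(a.female_id, 0) + 1
        a.attempt_index = idx[a.female_id]
    for a in kept_all + removed_all:
        a.fate = fate_by_attempt.get(f"{a.female_id}-{a.attempt_index}", a.fate)
    counts["attempts_kept"] = len(kept_all)
    counts["attempts_removed"] = len(removed_all)
    return kept_all, removed_all, cleaned, counts


def attempt_windows(trajectory, attempt):
    """(laying fixes, incubation fixes) DataFrames for one attempt."""
    fx = trajectory.fixes
    dates = fx["timestamp"].dt.date
    laying = fx.loc[(dates >= attempt.laying_onset) & (dates < attempt.incubation_onset)]
    incub = fx.loc[(dates >= attempt.incubation_onset) & (dates < attempt.incubation_end)]
    return laying, incub


def prospect_attempt(trajectory, attempt, cfg: PipelineConfig):
    """CLPs, classified/assigned recesses, and the prospecting summary."""
    laying, incub = attempt_windows(trajectory, attempt)
    if laying.empty:
        laying = incub.iloc[:1]
    clps = prospecting.cluster_laying_locations(
        laying, linkage_radius_m=cfg.linkage_radius_m, mode=trajectory.mode)
    rec = prospecting.classify_recesses(
        incub, attempt.nest_xy, threshold_m=cfg.recess_threshold_m, mode=trajectory.mode)
    clps, rec = prospecting.count_revisits(
        clps, rec, buffer_radius_m=cfg.buffer_radius_m, mode=trajectory.mode)
    summary = prospecting.summarize_prospecting(
        f"{attempt.female_id}-{attempt.attempt_index}", clps, rec)
    return clps, rec, summary


def build_used_available(trajectory, attempt, rec, land, surfaces, cfg, rng):
    """dBBMM 95% range, available sample, and the covariate-extracted
    used/available table for one attempt."""
    _, incub = attempt_windows(trajectory, attempt)
    ud, mask, _ = home_range.dbbmm_range(
        incub["timestamp"].to_numpy(), incub[["x", "y"]].to_numpy(float),
        window=cfg.dbbmm_window, margin=cfg.dbbmm_margin,
        error_m=cfg.dbbmm_error_m, grid_resolution=cfg.grid_resolution_m)
    avail = home_range.sample_available(mask, ud, n=cfg.n_available, rng=rng)
    used = rec.loc[rec["is_recess"] & rec["clp_id"].notna(), ["x", "y"]].to_numpy(float)
    pts = np.vstack([used, avail]) if len(used) else avail
    cov = landscape.extract_covariates(pts, land, surfaces, nest_xy=attempt.nest_xy)
    cov.insert(0, "used", [1] * len(used) + [0] * len(avail))
    cov.insert(0, "female_id", attempt.female_id)
    cov.insert(1, "attempt_id", f"{attempt.female_id}-{attempt.attempt_index}")
    return cov.loc[cov["error"] == ""].drop(columns="error"), ud, mask


RSF_COVARIATES = ["dist_nest", "dist_water", "dist_pine", "dist_hardwood",
                  "dist_mixed", "dist_open", "dist_shrub", "dist_road"]


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Simulate a population and run every analysis stage, writing summary
    tables under ``outdir``.  Returns the run manifest (also written as
    JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest = {"config": cfg.to_dict(), "config_hash": chash, "stages": {}}

    land, roads, trajectories, fates, truths = generate_population(cfg.sim)
    landscape.write_ascii_grid(land, outdir / "landcover.asc", outdir / "landcover_legend.json")
    (outdir / "roads.geojson").write_text(json.dumps(landscape.roads_to_geojson(roads)))
    gps.write_fixes(trajectories, outdir / "fixes.csv")
    write_truths(truths, outdir / "truth.jsonl")
    manifest["stages"]["simulate"] = {"n_females": cfg.sim.n_females,
                                      "n_attempts": len(truths)}

    kept, removed, cleaned, seg_counts = segment_attempts(trajectories, truths, cfg)
    manifest["stages"]["segment"] = seg_counts
    att_rows = [{"attempt_id": f"{a.female_id}-{a.attempt_index}",
                 "female_id": a.female_id, "attempt_index": a.attempt_index,
                 "nest_x": a.nest_xy[0], "nest_y": a.nest_xy[1],
                 "laying_onset": a.laying_onset.isoformat(),
                 "incubation_onset": a.incubation_onset.isoformat(),
                 "incubation_end": a.incubation_end.isoformat(),
                 "incubation_days": a.incubation_days, "fate": a.fate}
                for a in kept]
    attempts_df = pd.DataFrame(att_rows).sort_values("attempt_id")
    _write(attempts_df, outdir / "attempts.csv", chash)

    surfaces = landscape.build_surfaces(land, roads)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    prosp_rows, ua_parts = [], []
    n_recess_total = 0
    for a in sorted(kept, key=lambda a: (a.female_id, a.attempt_index)):
        traj = cleaned[a.female_id]
        clps, rec, summary = prospect_attempt(traj, a, cfg)
        n_recess_total += summary.total_recesses
        prosp_rows.append(dataclasses.asdict(summary))
        ua, _, _ = build_used_available(traj, a, rec, land, surfaces, cfg, rng)
        ua_parts.append(ua)
    prosp_df = pd.DataFrame(prosp_rows).sort_values("attempt_id")
    _write(prosp_df, outdir / "prospecting.csv", chash)
    manifest["stages"]["prospect"] = {
        "n_recesses": n_recess_total,
        "mean_proportion_to_clp": round(float(prosp_df["proportion_to_clp"].mean()), 6),
        "mean_n_clp_visited": round(float(prosp_df["n_clp_visited"].mean()), 6)}

    ua_df = pd.concat(ua_parts, ignore_index=True)
    _write(ua_df.round(6), outdir / "used_available.csv", chash)
    rsf = models.fit_rsf(ua_df, RSF_COVARIATES, ua_df["female_id"], r_max=cfg.r_max)
    rsf_out = {"config_hash": chash, "covariates": rsf.covariates,
               "beta": [round(float(b), 6) for b in rsf.beta],
               "se": [round(float(s), 6) for s in rsf.se],
               "sigma_b2": round(rsf.sigma_b2, 6), "n_used": rsf.n_used,
               "n_available": rsf.n_available, "dropped": rsf.dropped}
    (outdir / "rsf_fit.json").write_text(json.dumps(rsf_out, indent=1))
    manifest["stages"]["rsf"] = {"n_used": rsf.n_used, "n_available": rsf.n_available}

    fate_map = dict(zip(fates["attempt_id"], fates["fate"]))
    prosp_df["fate"] = prosp_df["attempt_id"].map(fate_map)
    fdf = prosp_df.dropna(subset=["fate"])
    post = models.fit_nest_fate(
        fdf["fate"], fdf[["proportion_to_clp", "n_clp_visited"]],
        fdf["attempt_id"].str.rsplit("-", n=1).str[0],
        chains=cfg.mcmc_chains, iterations=cfg.mcmc_iterations,
        burn_in=cfg.mcmc_burn_in, seed=cfg.seed + 2)
    ame = models.marginal_effect(post, fdf[["proportion_to_clp", "n_clp_visited"]],
                                 fdf["attempt_id"].str.rsplit("-", n=1).str[0],
                                 covariate="n_clp_visited")
    fate_out = {"config_hash": chash, "converged": post.converged,
                "sigma_b2": round(post.sigma_b2_mean, 6),
                "marginal_effect_pct_per_clp": round(ame, 6),
                "params": {nm: {"mean": round(float(m), 6),
                                "ci": [round(float(l), 6), round(float(u), 6)],
                                "pd": round(float(p), 6), "rhat": round(float(r), 6)}
                           for nm, m, l, u, p, r in zip(
                               post.params, post.mean, post.ci_lower,
                               post.ci_upper, post.pd, post.rhat)}}
    (outdir / "fate_fit.json").write_text(json.dumps(fate_out, indent=1))
    manifest["stages"]["fate"] = {"n_attempts": len(fdf), "converged": post.converged}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", manifest["stages"])
    return manifest


def _write(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
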