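"""Fit the used/available resource-selection function.

Used points are incubation recesses that returned to a CLP; available
points come from 04_home_range.py.  Covariates are distances to the six
landcover classes, secondary roads, and the nest, screened for Pearson
collinearity at |r| > 0.6 and rescaled by two standard deviations, then fit
with a random-intercept logistic GLMM.  Negative coefficients mean
selection for proximity.  Writes the fit and a coefficient plot.
"""

import argparse
import importlib
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from nestprospect import gps, landscape, models
from nestprospect.pipeline import RSF_COVARIATES, PipelineConfig, prospect_attempt

load_attempts = importlib.import_module("03_prospect").load_attempts


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = PipelineConfig()

    data = args.results / "data"
    land = landscape.read_ascii_grid(data / "landcover.asc", data / "landcover_legend.json")
    roads = landscape.roads_from_geojson(json.loads((data / "roads.geojson").read_text()))
    surfaces = landscape.build_surfaces(land, roads)
    trajectories, _ = gps.read_fixes(data / "fixes.csv")
    cleaned = {t.female_id: gps.filter_dop(t, cfg.dop_max) for t in trajectories}
    attempts = {f"{a.female_id}-{a.attempt_index}": a
                for a in load_attempts(args.results / "attempts.csv")}
    avail = pd.read_csv(args.results / "available_points.csv")

    parts = []
    for aid, a in attempts.items():
        _, rec, _ = prospect_attempt(cleaned[a.female_id], a, cfg)
        used = rec.loc[rec["is_recess"] & rec["clp_id"].notna(), ["x", "y"]]
        av = avail.loc[avail["attempt_id"] == aid, ["x", "y"]]
        pts = pd.concat([used, av], ignore_index=True).to_numpy(float)
        cov = landscape.extract_covariates(pts, land, surfaces, nest_xy=a.nest_xy)
        cov.insert(0, "used", [1] * len(used) + [0] * len(av))
        cov.insert(0, "female_id", a.female_id)
        parts.append(cov.loc[cov["error"] == ""].drop(columns="error"))
    ua = pd.concat(parts, ignore_index=True)

    fit = models.fit_rsf(ua, RSF_COVARIATES, ua["female_id"], r_max=cfg.r_max)
    out = {"covariates": fit.covariates,
           "beta": dict(zip(["intercept", *fit.covariates], fit.beta.round(4))),
           "se": dict(zip(["intercept", *fit.covariates], fit.se.round(4))),
           "sigma_b2": round(fit.sigma_b2, 4), "n_used": fit.n_used,
           "n_available": fit.n_available, "dropped": fit.dropped}
    (args.results / "rsf_fit.json").write_text(json.dumps(out, indent=1))

    t = fit.table().drop(index="intercept").iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(t["beta"], range(len(t)), xerr=1.96 * t["se"], fmt="o", color="k")
    ax.axvline(0, ls="--", lw=0.8, color="gray")
    ax.set_yticks(range(len(t)), t.index)
    ax.set_xlabel("selection coefficient (2-SD scale; negative = closer)")
    fig.tight_layout()
    (args.results / "figures").mkdir(exist_ok=True)
    fig.savefig(args.results / "figures" / "rsf_coefficients.png", dpi=150)

    print(f"RSF on {fit.n_used} used / {fit.n_available} available points "
          f"({len(attempts)} ranges); dropped for collinearity: {fit.dropped or 'none'}")
    print(fit.table().round(3))
    print(f"wrote {args.results / 'rsf_fit.json'} and figures/rsf_coefficients.png")


if __name__ == "__main__":
    main()
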