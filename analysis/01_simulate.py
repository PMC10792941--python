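"""Simulate the study population: landscape, GPS trajectories, nest fates.

Writes the raw inputs every later step consumes — a fix table, a landcover
raster with roads, and the per-attempt ground truth — under results/data/.
"""

import argparse
import json
from pathlib import Path

from nestprospect import gps, landscape
from nestprospect.synthetic import SimConfig, generate_population, write_truths


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-females", type=int, default=20)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimConfig(n_females=args.n_females, seed=args.seed)
    land, roads, trajectories, fates, truths = generate_population(cfg)

    out = args.results / "data"
    out.mkdir(parents=True, exist_ok=True)
    gps.write_fixes(trajectories, out / "fixes.csv")
    landscape.write_ascii_grid(land, out / "landcover.asc", out / "landcover_legend.json")
    (out / "roads.geojson").write_text(json.dumps(landscape.roads_to_geojson(roads)))
    write_truths(truths, out / "truth.jsonl")
    (out / "sim_config.json").write_text(json.dumps(
        {k: str(v) for k, v in cfg.__dict__.items()}, indent=1))

    n_fix = sum(len(t) for t in trajectories)
    n_succ = int((fates["fate"] == "success").sum())
    print(f"simulated {cfg.n_females} females / {len(truths)} nesting attempts, "
          f"{n_fix} GPS fixes on a {land.shape[0]}x{land.shape[1]} 30-m landscape")
    print(f"generative revisit rate p={cfg.p_revisit}; "
          f"{n_succ}/{len(truths)} nests successful")
    print(f"wrote fix table, raster, roads, and truth to {out}/")


if __name__ == "__main__":
    main()
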