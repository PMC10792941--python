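"""Segment each trajectory into laying and incubation and score recovery.

Reads results/data/, applies the DOP filter, detects incubation onset from
overnight fixes and laying onset from the 20-day pre-incubation window,
drops attempts incubated under 3 days, and compares every detected attempt
against the simulator's ground truth.  Writes results/attempts.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nestprospect import gps
from nestprospect.pipeline import PipelineConfig, segment_attempts
from nestprospect.synthetic import read_truths


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    trajectories, report = gps.read_fixes(args.results / "data" / "fixes.csv")
    truths = read_truths(args.results / "data" / "truth.jsonl")
    kept, removed, cleaned, counts = segment_attempts(trajectories, truths, PipelineConfig())

    tru = {t.female_id: t for t in truths}
    rows = []
    for a in kept:
        t = tru[a.female_id]
        rows.append({
            "attempt_id": f"{a.female_id}-{a.attempt_index}", "female_id": a.female_id,
            "nest_x": round(a.nest_xy[0], 3), "nest_y": round(a.nest_xy[1], 3),
            "laying_onset": a.laying_onset.isoformat(),
            "incubation_onset": a.incubation_onset.isoformat(),
            "incubation_end": a.incubation_end.isoformat(),
            "incubation_days": a.incubation_days, "fate": a.fate,
            "onset_error_days": (a.incubation_onset - t.true_incubation_onset).days,
            "laying_error_days": (a.laying_onset - t.true_laying_onset).days,
            "nest_error_m": round(float(np.hypot(a.nest_xy[0] - t.true_nest_xy[0],
                                                 a.nest_xy[1] - t.true_nest_xy[1])), 2),
        })
    df = pd.DataFrame(rows).sort_values("attempt_id")
    args.results.mkdir(exist_ok=True)
    df.to_csv(args.results / "attempts.csv", index=False)

    print(f"DOP filter kept {counts['fixes_kept']}/{counts['fixes_in']} fixes; "
          f"{counts['attempts_kept']} attempts kept, {counts['attempts_removed']} "
          f"removed (< 3 incubation days)")
    print(f"incubation onset exact for {(df['onset_error_days'] == 0).mean():.0%} "
          f"of attempts; laying onset within 1 day for "
          f"{(df['laying_error_days'].abs() <= 1).mean():.0%}; "
          f"median nest error {df['nest_error_m'].median():.1f} m")
    print(f"wrote {args.results / 'attempts.csv'}")


if __name__ == "__main__":
    main()
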