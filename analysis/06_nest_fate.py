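"""Fit the Bayesian nest-fate model.

Nest fate (success/fail) is modelled as Bernoulli with standardized
proportion-of-recesses-to-CLP and number-of-CLPs-visited covariates and a
female random intercept, sampled with 4 MCMC chains of 8000 iterations
(1000 burn-in).  Reports posterior means, 95% credible intervals,
probability of direction, split R-hat, and the average marginal effect of
one additional CLP visited on the probability of success.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from nestprospect import models


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--chains", type=int, default=4)
    ap.add_argument("--iterations", type=int, default=8000)
    ap.add_argument("--burn-in", type=int, default=1000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    pros = pd.read_csv(args.results / "prospecting.csv")
    attempts = pd.read_csv(args.results / "attempts.csv")
    df = pros.merge(attempts[["attempt_id", "female_id", "fate"]], on="attempt_id")
    df = df.loc[df["fate"].isin(["success", "fail"])]

    post = models.fit_nest_fate(
        df["fate"], df[["proportion_to_clp", "n_clp_visited"]], df["female_id"],
        chains=args.chains, iterations=args.iterations, burn_in=args.burn_in,
        seed=args.seed)
    ame = models.marginal_effect(post, df[["proportion_to_clp", "n_clp_visited"]],
                                 df["female_id"], covariate="n_clp_visited")

    out = {"n_attempts": int(len(df)), "converged": post.converged,
           "sigma_b2": round(post.sigma_b2_mean, 4),
           "marginal_effect_pct_per_clp": round(ame, 3),
           "params": {nm: {"mean": round(float(m), 4),
                           "ci_95": [round(float(l), 4), round(float(u), 4)],
                           "pd": round(float(p), 4), "rhat": round(float(r), 4)}
                      for nm, m, l, u, p, r in zip(post.params, post.mean,
                                                   post.ci_lower, post.ci_upper,
                                                   post.pd, post.rhat)}}
    (args.results / "fate_fit.json").write_text(json.dumps(out, indent=1))

    print(f"nest-fate model on {len(df)} attempts "
          f"({(df['fate'] == 'success').mean():.0%} successful); "
          f"converged={post.converged}")
    print(post.table().round(3))
    print(f"probability of success changes by {ame:+.1f} percentage points "
          f"per additional CLP visited")
    print(f"wrote {args.results / 'fate_fit.json'}")


if __name__ == "__main__":
    main()
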