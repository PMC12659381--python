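#!/usr/bin/env python
"""Fit candidate hazard families to the bundle's survival observations.

For every disease, arm and bound series the four candidate families are
fitted by binomial maximum likelihood; the table reports the selected
family and its parameters next to the generator's true family.  At
digitised-cohort sample sizes (n_eff = 200 per time point) families with
similar survival shapes are often statistically interchangeable, so the
selected family can differ from the generating one while fitting the
observed curve essentially as well; larger cohorts recover the true
family reliably.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from ncd_excess import fit_survival_model, generate_inputs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/survival_fits.csv"))
    args = ap.parse_args()

    bundle, truth = generate_inputs(args.seed, profile="paper_like")
    rows = []
    for disease, obs in bundle.survival_observations.items():
        by_series = {}
        for o in obs:
            by_series.setdefault((o.arm, o.source), []).append(o)
        for (arm, source), series in sorted(by_series.items()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ranked = fit_survival_model(series)
            best, ll = ranked[0]
            bound = source.split(":")[-1]
            true_models = [m for m in truth.hazards[disease][arm] if m.bound == bound]
            rows.append({
                "disease": disease, "arm": arm, "bound": bound,
                "selected_family": best.family,
                "true_family": true_models[0].family if true_models else "?",
                "params": "; ".join(f"{k}={v:.4g}" for k, v in best.params.items()),
                "loglik": round(ll, 2),
            })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    hits = (df.selected_family == df.true_family).mean()
    print(df.to_string(index=False))
    print(f"\ncorrect family selected in {100 * hits:.0f}% of "
          f"{len(df)} series (n_eff = 200 per observation)")


if __name__ == "__main__":
    main()
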