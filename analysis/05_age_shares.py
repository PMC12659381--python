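#!/usr/bin/env python
"""Age structure of projected excess deaths.

Computes the share of excess deaths among people aged 50 and over, both
from this analysis's synthetic projection output (step 04) and from the
published Gaza projection tables bundled with the package.
"""

import argparse
from pathlib import Path

import pandas as pd

from ncd_excess import age_share
from ncd_excess.cohort import SCENARIOS
from ncd_excess.reference_tables import EXCESS_BY_AGE_TOTAL


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--projections", type=Path, default=Path("results/projections"))
    ap.add_argument("--out", type=Path, default=Path("results/age_shares.csv"))
    args = ap.parse_args()

    rows = []
    for scenario in SCENARIOS:
        rows.append({
            "scenario": scenario,
            "source": "published_tables",
            "share_ge50_pct": age_share(EXCESS_BY_AGE_TOTAL[scenario], "50-59"),
        })

    summary_path = args.projections / "summary_all.csv"
    if summary_path.exists():
        table = pd.read_csv(summary_path)
        for scenario in SCENARIOS:
            age_rows = table[
                (table.scenario == scenario)
                & (table.disease == "all")
                & (table.stratum != "all")
                & (table.sub_period == "total")
            ]
            shares = dict(zip(age_rows.stratum, age_rows["mean"]))
            rows.append({
                "scenario": scenario,
                "source": "synthetic_projection",
                "share_ge50_pct": age_share(shares, "50-59"),
            })
    else:
        print(f"note: {summary_path} not found; run 04_project_scenarios.py "
              "for the synthetic shares")

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
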