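"""Summaries, disparities, significance, and masking.

Aggregates HALE draws across sexes and counties with population weights,
derives point estimates and 95% uncertainty intervals from the draws,
flags significant 2009-2019 changes by the posterior-probability rule,
masks county-race populations below the mean-annual-population threshold,
and tabulates county-level disparity statistics.
"""

import logging
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from countyhale.pipeline import run_stage  # noqa: E402


def main():
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    args = common.parse_args(__doc__)
    cfg = common.load_config(args)
    run_stage("summarize", cfg)
    out = Path(cfg.out_dir)
    nat = pd.read_csv(out / "national_summary.csv")
    disp = pd.read_csv(out / "disparities.csv")
    chg = pd.read_csv(out / "changes.csv")
    y1 = cfg.change_years[1]
    last = nat[nat.year == y1]
    print(f"national HALE in {y1} by population:")
    for _, row in last.iterrows():
        print(
            f"  {row['race']:>8}: {row['hale']:.1f} "
            f"({row['hale_lower']:.1f}-{row['hale_upper']:.1f}) years; "
            f"{row['years_poor']:.1f} years ({100 * row['prop_poor']:.1f}%) "
            f"in poor health"
        )
    tot = disp[disp.race == "total"].iloc[0]
    print(
        f"county HALE range ({y1}, total population): "
        f"{tot['range']:.1f} years [{tot['min']:.1f}-{tot['max']:.1f}], "
        f"median {tot['median']:.1f} "
        f"(IQR {tot['iqr_lower']:.1f}-{tot['iqr_upper']:.1f})"
    )
    tot_chg = chg[chg.race == "total"].iloc[0]
    print(
        f"significant HALE changes {tot_chg['years']}: "
        f"{tot_chg['n_decline']} of {tot_chg['n_counties']} counties "
        f"declined ({tot_chg['pct_decline']}%), "
        f"{tot_chg['n_increase']} increased ({tot_chg['pct_increase']}%)"
    )


if __name__ == "__main__":
    main()
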