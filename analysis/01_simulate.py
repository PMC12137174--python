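"""Generate the synthetic study inputs.

Produces, under the output directory: the merged-county geography and its
adjacency, stratum populations, county sociodemographic covariates,
survey-style indicator observations at mixed aggregation levels,
state-level YLD benchmarks per cause with draws, abridged life tables, and
the ground-truth surfaces that downstream recovery checks compare against.
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
    run_stage("simulate", cfg)
    pop = pd.read_csv(f"{cfg.out_dir}/population.csv")
    obs = pd.read_csv(f"{cfg.out_dir}/indicator_obs.csv")
    print(
        f"simulated {cfg.synthetic.n_counties} counties in "
        f"{cfg.synthetic.n_states} states; total population "
        f"{pop['population'].sum() / 1e6:.2f} m; "
        f"{len(obs)} indicator observations "
        f"({(obs['level'] == 'state').mean():.0%} state-aggregated)"
    )


if __name__ == "__main__":
    main()
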