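"""Estimate cause-group YLD rates at county-race resolution.

Per cause: one regression of the log state benchmark on log YLL rates,
indicator prevalences, and covariates per input draw (model m consuming
input draw m), each contributing its share of prediction draws; causes are
then summed draw-wise into the all-cause YLD cube.
"""

import logging
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from countyhale import io as chio  # noqa: E402
from countyhale.pipeline import run_stage  # noqa: E402


def main():
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    args = common.parse_args(__doc__)
    cfg = common.load_config(args)
    run_stage("fit_ylds", cfg)
    cube = chio.load_cube(Path(cfg.out_dir) / "yld_all_cause.cube")
    means = pd.read_csv(Path(cfg.out_dir) / "yld_cause_means.csv")
    print(
        f"all-cause YLD cube: {cube.sizes['draw']} draws "
        f"({cube.attrs.get('n_models')} models x "
        f"{cube.attrs.get('draws_per_model')} per model), "
        f"mean rate {float(cube.mean()):.3f}; largest cause "
        f"{means.loc[means.mean_rate.idxmax(), 'cause']} "
        f"({means.mean_rate.max():.3f})"
    )


if __name__ == "__main__":
    main()
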