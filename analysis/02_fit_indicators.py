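"""Fit the small-area prevalence model for each health indicator.

Each indicator gets a hierarchical logit model with ICAR county, RW1 year,
RW1 age, and exchangeable race effects, fit by Laplace-approximate maximum
marginal likelihood on the aggregation-consistent binomial likelihood.
Writes one posterior prevalence draw cube per indicator.
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from countyhale import io as chio  # noqa: E402
from countyhale.pipeline import run_stage  # noqa: E402


def main():
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    args = common.parse_args(__doc__)
    cfg = common.load_config(args)
    run_stage("fit_indicators", cfg)
    for ind in cfg.synthetic.indicators:
        cube = chio.load_cube(Path(cfg.out_dir) / f"prevalence_{ind}.cube")
        print(
            f"{ind}: {cube.sizes['draw']} prevalence draws, "
            f"posterior mean prevalence {float(cube.mean()):.3f}, "
            f"range [{float(cube.min()):.4f}, {float(cube.max()):.4f}]"
        )


if __name__ == "__main__":
    main()
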