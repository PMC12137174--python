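"""Rake all-cause YLD rates to the state benchmarks.

Scales county-race estimates multiplicatively so that, for every state,
sex, age group, year, and draw, their population-weighted average equals
the state benchmark exactly.
"""

import logging
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from countyhale import io as chio  # noqa: E402
from countyhale.pipeline import run_stage  # noqa: E402


def main():
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    args = common.parse_args(__doc__)
    cfg = common.load_config(args)
    run_stage("rake", cfg)
    before = chio.load_cube(Path(cfg.out_dir) / "yld_all_cause.cube")
    after = chio.load_cube(Path(cfg.out_dir) / "yld_all_cause_raked.cube")
    ratio = after.values / np.maximum(before.values, 1e-12)
    print(
        f"raked {after.sizes['draw']} draws; raking factors span "
        f"[{ratio.min():.3f}, {ratio.max():.3f}] "
        f"(median {np.median(ratio):.3f})"
    )


if __name__ == "__main__":
    main()
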