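"""Shared argument parsing and configuration loading for the drivers."""

import argparse

from countyhale.pipeline import PipelineConfig


def parse_args(description: str):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--config", default=None, help="YAML pipeline config")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/pipeline")
    return ap.parse_args()


def load_config(args) -> PipelineConfig:
    if args.config:
        d = PipelineConfig.from_yaml(args.config).to_dict()
    else:
        d = PipelineConfig().to_dict()
    d["seed"] = args.seed
    d["out_dir"] = args.out_dir
    return PipelineConfig.from_dict(d)
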