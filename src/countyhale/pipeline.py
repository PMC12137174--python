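"""Pipeline orchestration: configuration, staged execution, manifests, CLI.

Stages (in dependency order): ``simulate`` -> ``fit_indicators`` ->
``fit_ylds`` -> ``rake`` -> ``hale`` -> ``summarize``; ``all`` runs the
chain.  Each stage writes its artifacts plus a JSON manifest recording the
configuration hash, the stage seed, input-file hashes, and output-file
hashes and row counts.  A stage refuses to run when an upstream manifest
is missing or an input file no longer matches the hash its producer
recorded, naming the stage to rerun.  With a fixed master seed the whole
chain is deterministic and reruns are byte-identical.

Per-stage random seeds are derived from the master seed and the stage name
(CRC32 of the name mixed into the seed), so stages are decoupled: rerunning
one stage never changes another's stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import io as chio
from .observations import IndicatorObservations
from .raking import apply_raking
from .sae_indicators import (
    FitConfig,
    build_effect_structure,
    draw_posterior,
    fit_indicator_model,
)
from .strata import DRAW_DIM
from .sullivan_hale import hale_sullivan, poor_health_summaries
from .summaries import (
    aggregate_weighted,
    compare,
    county_disparity_stats,
    mask_small,
    point_and_ui,
)
from .synthetic_data import (
    ObservationDesign,
    SyntheticConfig,
    make_geography,
    simulate_benchmarks,
    simulate_indicator_observations,
    simulate_life_tables,
    simulate_population,
    simulate_truth,
)
from .yld_model import CauseConfig, YldInputs, propagate_draws, sum_causes

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit_indicators", "fit_ylds", "rake", "hale", "summarize")

_DEPENDS = {
    "simulate": (),
    "fit_indicators": ("simulate",),
    "fit_ylds": ("simulate", "fit_indicators"),
    "rake": ("simulate", "fit_ylds"),
    "hale": ("simulate", "rake"),
    "summarize": ("simulate", "hale"),
}


class PipelineError(RuntimeError):
    """User-actionable pipeline failure (missing upstream, bad config)."""


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 1
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    observation: ObservationDesign = field(default_factory=ObservationDesign)
    fit: FitConfig = field(default_factory=FitConfig)
    cause: CauseConfig = field(init=False)
    n_models: int = 50
    draws_per_model: int = 20
    benchmark_noise_sd: float = 0.02
    mask_threshold: float = 1000.0
    change_years: tuple[int, int] = (2009, 2019)

    def __post_init__(self) -> None:
        self.cause = CauseConfig(
            causes=self.synthetic.causes,
            n_models=self.n_models,
            draws_per_model=self.draws_per_model,
        )
        for y in self.change_years:
            if y not in self.synthetic.years:
                raise PipelineError(
                    f"change year {y} outside the configured year range"
                )

    @property
    def total_draws(self) -> int:
        return self.cause.total_draws

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("cause")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("synthetic", SyntheticConfig),
            ("observation", ObservationDesign),
            ("fit", FitConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = _dataclass_from_dict(sub, d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dataclass_from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        val = d[f.name]
        if dataclasses.is_dataclass(f.type) and isinstance(val, dict):
            val = _dataclass_from_dict(f.type, val)
        if isinstance(val, list):
            val = tuple(
                tuple(v) if isinstance(v, list) else v for v in val
            )
        kwargs[f.name] = val
    # nested EffectVariances come through as dicts
    from .synthetic_data import EffectVariances

    for key in ("prevalence_variances", "mortality_variances", "yld_variances"):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = EffectVariances(**kwargs[key])
    return cls(**kwargs)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (master * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# manifests

def _hash_path(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for sub in sorted(path.rglob("*")):
            if sub.is_file():
                h.update(sub.name.encode())
                h.update(sub.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _row_count(path: Path) -> int:
    if path.is_dir():
        values = path / "values.npy"
        if values.exists():
            arr = np.load(values, mmap_mode="r")
            return int(arr.shape[0])
        return sum(1 for _ in path.rglob("*") if _.is_file())
    if path.suffix == ".csv":
        with open(path) as fh:
            return max(sum(1 for _ in fh) - 1, 0)
    return 1


def _write_manifest(
    out_dir: Path, stage: str, config: PipelineConfig,
    inputs: list[Path], outputs: list[Path],
) -> Path:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": stage_seed(config.seed, stage),
        "inputs": {str(p.relative_to(out_dir)): _hash_path(p) for p in inputs},
        "outputs": {
            str(p.relative_to(out_dir)): {
                "sha256": _hash_path(p),
                "rows": _row_count(p),
            }
            for p in outputs
        },
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _check_upstream(out_dir: Path, stage: str) -> None:
    for dep in _DEPENDS[stage]:
        mpath = out_dir / f"manifest_{dep}.json"
        if not mpath.exists():
            raise PipelineError(
                f"stage {stage!r} needs outputs of {dep!r}; run stage "
                f"{dep!r} first"
            )
        manifest = json.loads(mpath.read_text())
        for rel, info in manifest["outputs"].items():
            p = out_dir / rel
            if not p.exists():
                raise PipelineError(
                    f"input {rel} (from stage {dep!r}) is missing; rerun "
                    f"stage {dep!r}"
                )
            if _hash_path(p) != info["sha256"]:
                raise PipelineError(
                    f"input {rel} does not match the hash recorded by stage "
                    f"{dep!r}; rerun stage {dep!r}"
                )


# ---------------------------------------------------------------------------
# shared loaders

def _load_context(cfg: PipelineConfig, out_dir: Path):
    geography = chio.read_geography(out_dir / "geography.csv")
    strata = cfg.synthetic.strata_for(geography)
    populations = chio.read_population(out_dir / "population.csv", strata)
    covariates = chio.read_covariates(out_dir / "covariates.csv")
    return geography, strata, populations, covariates


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig, out_dir: Path) -> tuple[list, list]:
    seed = stage_seed(cfg.seed, "simulate")
    geography = make_geography(
        cfg.synthetic.n_counties, cfg.synthetic.n_states, seed=seed,
        rewire_fraction=cfg.synthetic.rewire_fraction,
    )
    truth = simulate_truth(geography, cfg.synthetic, seed)
    populations = simulate_population(geography, cfg.synthetic, seed)
    obs = simulate_indicator_observations(
        truth, populations, cfg.observation, seed
    )
    benchmarks = simulate_benchmarks(
        truth, populations, n_draws=cfg.total_draws,
        noise_sd=cfg.benchmark_noise_sd, seed=seed,
    )
    lifetables = simulate_life_tables(truth)

    chio.write_geography(geography, out_dir / "geography.csv")
    chio.write_population(populations, out_dir / "population.csv")
    chio.write_covariates(truth.covariates, out_dir / "covariates.csv")
    chio.write_indicator_obs(obs, out_dir / "indicator_obs.csv")
    chio.save_benchmarks(benchmarks, out_dir / "benchmarks.cube")
    chio.write_lifetables(lifetables, out_dir / "lifetables.csv")
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    chio.write_surface(truth.mx, truth_dir / "mx.csv", "mx")
    for ind, surf in truth.prevalence.items():
        chio.write_surface(surf, truth_dir / f"prevalence_{ind}.csv", "p")
    for cause, surf in truth.yll.items():
        chio.write_surface(surf, truth_dir / f"yll_{cause}.csv", "yll")
    for cause, surf in truth.yld.items():
        chio.write_surface(surf, truth_dir / f"yld_{cause}.csv", "yld")
    outputs = [
        out_dir / "geography.csv", out_dir / "population.csv",
        out_dir / "covariates.csv", out_dir / "indicator_obs.csv",
        out_dir / "benchmarks.cube", out_dir / "lifetables.csv",
        *sorted(truth_dir.glob("*.csv")),
    ]
    return [], outputs


def _stage_fit_indicators(cfg: PipelineConfig, out_dir: Path):
    seed = stage_seed(cfg.seed, "fit_indicators")
    geography, strata, populations, covariates = _load_context(cfg, out_dir)
    strata_edu = cfg.synthetic.strata_for(geography, education=True)
    obs = chio.read_indicator_obs(out_dir / "indicator_obs.csv", strata_edu)
    outputs = []
    fit_rows = []
    for j, (ind, o) in enumerate(obs.items()):
        structure = build_effect_structure(geography, strata_edu, covariates)
        fitted = fit_indicator_model(o, structure, cfg.fit)
        cube = draw_posterior(
            fitted, structure, n_draws=cfg.total_draws, seed=seed + j
        )
        path = out_dir / f"prevalence_{ind}.cube"
        chio.save_cube(cube, path)
        outputs.append(path)
        se = fitted.fixed_effect_se()
        for name, est in fitted.fixed_effects.items():
            fit_rows.append(
                {
                    "indicator": ind, "term": name, "estimate": est,
                    "se": se[name], "converged": fitted.converged,
                    "grad_norm": fitted.grad_norm,
                }
            )
    pd.DataFrame(fit_rows).to_csv(
        out_dir / "indicator_fit_summary.csv", index=False
    )
    outputs.append(out_dir / "indicator_fit_summary.csv")
    inputs = [
        out_dir / "indicator_obs.csv", out_dir / "geography.csv",
        out_dir / "population.csv", out_dir / "covariates.csv",
    ]
    return inputs, outputs


def _stage_fit_ylds(cfg: PipelineConfig, out_dir: Path):
    seed = stage_seed(cfg.seed, "fit_ylds")
    geography, strata, populations, covariates = _load_context(cfg, out_dir)
    benchmarks = chio.load_benchmarks(out_dir / "benchmarks.cube")
    indicator_cubes = {
        ind: chio.load_cube(out_dir / f"prevalence_{ind}.cube")
        for ind in cfg.synthetic.indicators
    }
    total = None
    cause_means = []
    for c_i, cause in enumerate(cfg.cause.causes):
        yll = chio.read_surface(
            out_dir / "truth" / f"yll_{cause}.csv", strata, "yll"
        )
        inputs_c = YldInputs(
            strata=strata, geography=geography,
            benchmark=benchmarks[cause], yll=yll,
            indicator_cubes=indicator_cubes, covariates=covariates,
            populations=populations,
        )
        cube = propagate_draws(cause, inputs_c, cfg.cause, seed + c_i)
        cause_means.append(
            {"cause": cause, "mean_rate": float(cube.mean())}
        )
        total = cube if total is None else sum_causes([total, cube])
        logger.info("cause %s done (%d/%d)", cause, c_i + 1, len(cfg.cause.causes))
    path = out_dir / "yld_all_cause.cube"
    chio.save_cube(total, path)
    pd.DataFrame(cause_means).to_csv(
        out_dir / "yld_cause_means.csv", index=False
    )
    inputs = [
        out_dir / "benchmarks.cube",
        *[out_dir / f"prevalence_{i}.cube" for i in cfg.synthetic.indicators],
    ]
    return inputs, [path, out_dir / "yld_cause_means.csv"]


def _stage_rake(cfg: PipelineConfig, out_dir: Path):
    geography, strata, populations, _ = _load_context(cfg, out_dir)
    cube = chio.load_cube(out_dir / "yld_all_cause.cube")
    benchmarks = chio.load_benchmarks(out_dir / "benchmarks.cube")
    all_cause_bench = sum(benchmarks.values()).clip(0.0, 1.0)
    raked = apply_raking(cube, populations, geography, all_cause_bench)
    path = out_dir / "yld_all_cause_raked.cube"
    chio.save_cube(raked, path)
    inputs = [out_dir / "yld_all_cause.cube", out_dir / "benchmarks.cube"]
    return inputs, [path]


def _stage_hale(cfg: PipelineConfig, out_dir: Path):
    geography, strata, populations, _ = _load_context(cfg, out_dir)
    lifetables = chio.read_lifetables(out_dir / "lifetables.csv", strata)
    raked = chio.load_cube(out_dir / "yld_all_cause_raked.cube")
    hale = hale_sullivan(lifetables, raked)
    # HALE at birth: the first age group's value, one series per
    # (county, race, sex, year, draw); by-age summaries are also written
    hale_birth = hale.isel(age=0, drop=True)
    hale_birth.attrs.update(raked.attrs)
    path = out_dir / "hale_draws.cube"
    chio.save_cube(hale_birth, path)
    by_age = point_and_ui(hale)
    by_age.to_dataframe().reset_index().to_csv(
        out_dir / "hale_by_age.csv", index=False
    )
    e0 = lifetables["e"].isel(age=0, drop=True)
    chio.write_surface(e0, out_dir / "life_expectancy.csv", "e0")
    inputs = [out_dir / "lifetables.csv", out_dir / "yld_all_cause_raked.cube"]
    return inputs, [
        path, out_dir / "hale_by_age.csv", out_dir / "life_expectancy.csv",
    ]


def _stage_summarize(cfg: PipelineConfig, out_dir: Path):
    geography, strata, populations, _ = _load_context(cfg, out_dir)
    hale = chio.load_cube(out_dir / "hale_draws.cube")
    lifetables = chio.read_lifetables(out_dir / "lifetables.csv", strata)
    e0 = lifetables["e"].isel(age=0, drop=True)
    pop_cry = populations.sum("age")  # (county, race, sex, year)
    masks = mask_small(populations, cfg.mask_threshold)

    # sexes combined, then county-race summaries
    hale_both = aggregate_weighted(hale, pop_cry, "sex")
    e0_both = (e0 * pop_cry).sum("sex") / pop_cry.sum("sex")
    summ = point_and_ui(hale_both)
    df = summ.to_dataframe().reset_index()
    df = df.merge(
        e0_both.rename("life_expectancy").to_series().reset_index(),
        on=["county", "race", "year"],
    )
    df["years_poor"] = df["life_expectancy"] - df["mean"]
    df["prop_poor"] = df["years_poor"] / df["life_expectancy"]
    mask_df = (
        masks.to_dataframe().reset_index()[
            ["county", "race", "masked", "mean_annual_population"]
        ]
    )
    df = df.merge(mask_df, on=["county", "race"])
    df = df.rename(columns={"mean": "hale"})
    df.to_csv(out_dir / "hale_summary.csv", index=False)

    # national aggregation: by race and total, per draw then summarized
    pop_cr_y = pop_cry.sum("sex")
    national_rows = []
    nat_by_race = aggregate_weighted(hale_both, pop_cr_y, "county")
    e0_race = (e0_both * pop_cr_y).sum("county") / pop_cr_y.sum("county")
    total = aggregate_weighted(hale_both, pop_cr_y, ("county", "race"))
    e0_total = (e0_both * pop_cr_y).sum(("county", "race")) / pop_cr_y.sum(
        ("county", "race")
    )
    y0, y1 = cfg.change_years
    for race in list(strata.races) + ["total"]:
        cube = nat_by_race.sel(race=race) if race != "total" else total
        e_series = e0_race.sel(race=race) if race != "total" else e0_total
        s = point_and_ui(cube)
        chg = compare(
            cube.sel(year=y1, drop=True), cube.sel(year=y0, drop=True)
        )
        for year in strata.years:
            e_val = float(e_series.sel(year=year))
            hale_mean = float(s["mean"].sel(year=year))
            yp, pp = poor_health_summaries(e_val, hale_mean)
            national_rows.append(
                {
                    "race": race, "year": year, "hale": hale_mean,
                    "hale_lower": float(s["lower"].sel(year=year)),
                    "hale_upper": float(s["upper"].sel(year=year)),
                    "life_expectancy": e_val,
                    "years_poor": yp, "prop_poor": pp,
                    "change_mean": float(chg.difference),
                    "change_significant": bool(chg.significant),
                }
            )
    pd.DataFrame(national_rows).to_csv(
        out_dir / "national_summary.csv", index=False
    )

    # county-level disparities and changes per race, total population
    disp_rows = []
    change_rows = []
    county_pop = pop_cr_y  # (county, race, year)
    hale_total_county = aggregate_weighted(hale_both, county_pop, "race")
    for race in list(strata.races) + ["total"]:
        if race == "total":
            cube = hale_total_county
            masked = (
                masks["masked"].sum("race") == len(strata.races)
            )  # total masked only if every race series is masked
        else:
            cube = hale_both.sel(race=race)
            masked = masks["masked"].sel(race=race)
        s = point_and_ui(cube.sel(year=y1, drop=True))
        chg = compare(
            cube.sel(year=y1, drop=True), cube.sel(year=y0, drop=True)
        )
        stats = county_disparity_stats(
            s["mean"], masked=masked,
            change_significant=chg.significant,
            change_sign=chg.difference,
        )
        stats["race"] = race
        stats["year"] = y1
        disp_rows.append(stats)
        change_rows.append(
            {
                "race": race, "years": f"{y0}-{y1}",
                "n_counties": stats["n_compared"],
                "n_increase": stats["n_significant_increase"],
                "n_decline": stats["n_significant_decline"],
                "pct_increase": stats["pct_significant_increase"],
                "pct_decline": stats["pct_significant_decline"],
            }
        )
    pd.DataFrame(disp_rows).to_csv(out_dir / "disparities.csv", index=False)
    pd.DataFrame(change_rows).to_csv(out_dir / "changes.csv", index=False)

    inputs = [
        out_dir / "hale_draws.cube", out_dir / "lifetables.csv",
        out_dir / "population.csv",
    ]
    outputs = [
        out_dir / "hale_summary.csv", out_dir / "national_summary.csv",
        out_dir / "disparities.csv", out_dir / "changes.csv",
    ]
    return inputs, outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit_indicators": _stage_fit_indicators,
    "fit_ylds": _stage_fit_ylds,
    "rake": _stage_rake,
    "hale": _stage_hale,
    "summarize": _stage_summarize,
}


def run_stage(stage: str, config: PipelineConfig) -> Path:
    """Run one stage, verify upstream manifests, write this stage's manifest."""
    if stage == "all":
        for s in STAGES:
            run_stage(s, config)
        return Path(config.out_dir)
    if stage not in _STAGE_FUNCS:
        raise PipelineError(
            f"unknown stage {stage!r}; choose from {STAGES + ('all',)}"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _check_upstream(out_dir, stage)
    t0 = time.perf_counter()
    inputs, outputs = _STAGE_FUNCS[stage](config, out_dir)
    manifest = _write_manifest(out_dir, stage, config, inputs, outputs)
    logger.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
    return manifest


# ---------------------------------------------------------------------------
# command-line interface

@click.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML pipeline configuration.")
@click.option("--stage", default="all",
              type=click.Choice(STAGES + ("all",)), show_default=True)
@click.option("--seed", type=int, default=None, help="Master seed override.")
@click.option("--out-dir", type=click.Path(), default=None)
@click.option("--draws", type=int, default=None,
              help="Total draws (n_models x draws_per_model kept fixed at "
                   "20 draws per model).")
@click.option("--mask-threshold", type=float, default=None)
@click.option("-v", "--verbose", is_flag=True)
def main(config_path, stage, seed, out_dir, draws, mask_threshold, verbose):
    """Run the synthetic HALE small-area estimation pipeline."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    try:
        cfg = (
            PipelineConfig.from_yaml(Path(config_path))
            if config_path
            else PipelineConfig()
        )
        overrides = {}
        if seed is not None:
            overrides["seed"] = seed
        if out_dir is not None:
            overrides["out_dir"] = out_dir
        if mask_threshold is not None:
            overrides["mask_threshold"] = mask_threshold
        if draws is not None:
            if draws % 20:
                raise PipelineError("--draws must be a multiple of 20")
            overrides["n_models"] = draws // 20
            overrides["draws_per_model"] = 20
        if overrides:
            d = cfg.to_dict()
            d.update(overrides)
            cfg = PipelineConfig.from_dict(d)
        run_stage(stage, cfg)
    except (PipelineError, click.ClickException) as err:
        click.echo(f"error: {err}", err=True)
        sys.exit(1)
    except Exception as err:  # internal failure
        logging.exception("internal error")
        click.echo(f"internal error: {err}", err=True)
        sys.exit(2)
    sys.exit(0)


if __name__ == "__main__":
    main()
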