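"""Cause-group YLD-rate models at county-race resolution.

Benchmark YLD rates are only available at state level, while the desired
estimates are at county-race level.  Each cause-group model regresses the
log state benchmark on a log-linear predictor built from county-race level
covariates — the cause's YLL rate (log), modelled indicator prevalences,
and sociodemographic covariates — under the aggregation-consistent
likelihood: the model's state-level mean is the log of the
population-weighted average of exp(linear predictor) over the state's
county-race strata.  Errors are Gaussian on the log scale (rates are
positive and multiplicative).

Uncertainty in the stochastic inputs is propagated by draw splitting:
``n_models`` (default 50) independent fits per cause, model m consuming
input draw m of every stochastic input; each fitted model then simulates
``draws_per_model`` (default 20) prediction draws (coefficient uncertainty
plus residual noise), concatenated in (model, draw) order into the cause's
1000-draw cube.  Summing the per-cause cubes draw-wise yields all-cause
YLD rates with cross-cause correlation preserved by draw index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import xarray as xr
from scipy.optimize import least_squares

from .strata import DRAW_DIM, StrataCoords, require_aligned, set_lineage
from .synthetic_data import Geography

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CauseConfig:
    """Cause list and the draw-splitting scheme."""

    causes: tuple[str, ...] = tuple(f"cause_{i + 1:02d}" for i in range(16))
    n_models: int = 50
    draws_per_model: int = 20

    def __post_init__(self) -> None:
        if self.n_models < 1 or self.draws_per_model < 1:
            raise ValueError("n_models and draws_per_model must be >= 1")

    @property
    def total_draws(self) -> int:
        return self.n_models * self.draws_per_model


@dataclass
class YldModelFit:
    """One fitted regression for one cause and one input draw."""

    cause: str
    input_draw: int
    coef: np.ndarray
    coef_names: tuple[str, ...]
    coef_cov: np.ndarray
    resid_var: float
    n_obs: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite coefficients")


@dataclass
class YldInputs:
    """Predictors and outcome for one cause's models.

    ``benchmark`` has dims (state, sex, age, year, draw); ``yll`` is a
    deterministic stratum surface; ``indicator_cubes`` map indicator name
    to a stratum draw cube; ``covariates`` has dims (covariate, county).
    """

    strata: StrataCoords
    geography: Geography
    benchmark: xr.DataArray
    yll: xr.DataArray
    indicator_cubes: dict[str, xr.DataArray]
    covariates: xr.DataArray
    populations: xr.DataArray


def _align_surface(da: xr.DataArray, strata: StrataCoords) -> np.ndarray:
    """Label-align a stratum surface to the strata grid, C order."""
    coords = strata.coords()
    sel = {d: coords[d] for d in strata.dims if d in da.dims}
    return (
        da.sel(sel).transpose(*[d for d in strata.dims if d in da.dims]).values
    )


def _design_matrix(
    strata: StrataCoords,
    yll: xr.DataArray,
    indicators: dict[str, xr.DataArray],
    covariates: xr.DataArray,
) -> tuple[np.ndarray, tuple[str, ...]]:
    idx = strata.index_arrays()
    yll_vals = _align_surface(yll, strata)
    cols = [
        np.ones(strata.n_strata),
        np.log(np.maximum(yll_vals.ravel(), 1e-12)),
    ]
    names = ["intercept", "log_yll"]
    # age-group main effects (first group as reference): YLD age profiles
    # are far shallower than YLL profiles, so the regression needs its own
    # age level on top of the YLL term
    labels = strata.age_grid.labels
    for a in range(1, strata.age_grid.n_groups):
        cols.append((idx["age"] == a).astype(float))
        names.append(f"age_{labels[a]}")
    for name, da in indicators.items():
        cols.append(_align_surface(da, strata).ravel())
        names.append(f"ind_{name}")
    for name in covariates["covariate"].values:
        vals = covariates.sel(county=list(strata.counties)).sel(
            covariate=name
        ).values
        cols.append(vals[idx["county"]])
        names.append(str(name))
    return np.column_stack(cols), tuple(names)


def _state_aggregator(
    strata: StrataCoords, geography: Geography, populations: xr.DataArray
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse map from flat strata to flat (state, sex, age, year) cells.

    Rows hold population weights normalized to sum to one; cells with zero
    population are dropped (with a warning) and reported via the returned
    row mask.
    """
    idx = strata.index_arrays()
    lookup = {c: i for i, c in enumerate(geography.county_ids)}
    state_codes = geography.state_codes
    s_of_stratum = state_codes[
        np.array([lookup[c] for c in strata.counties])
    ][idx["county"]]
    n_states = len(geography.states)
    nsx = len(strata.sexes)
    nag = strata.age_grid.n_groups
    nyr = len(strata.years)
    cell = (
        ((s_of_stratum * nsx + idx["sex"]) * nag + idx["age"]) * nyr
        + idx["year"]
    )
    w = _align_surface(populations, strata).ravel()
    n_cells = n_states * nsx * nag * nyr
    M = sp.coo_matrix(
        (w, (cell, np.arange(strata.n_strata))),
        shape=(n_cells, strata.n_strata),
    ).tocsr()
    rowsum = np.asarray(M.sum(axis=1)).ravel()
    keep = rowsum > 0
    if not np.all(keep):
        logger.warning(
            "excluding %d state cells with zero population", int((~keep).sum())
        )
    Mn = sp.diags(np.where(keep, 1.0 / np.where(keep, rowsum, 1.0), 0.0)) @ M
    return Mn.tocsr()[keep], keep


def fit_cause_model(
    benchmark_draw: xr.DataArray,
    yll_rates: xr.DataArray,
    indicator_draw: dict[str, xr.DataArray],
    covariates: xr.DataArray,
    populations: xr.DataArray,
    strata: StrataCoords,
    geography: Geography,
    cause: str = "cause",
    input_draw: int = 0,
) -> YldModelFit:
    """Fit one Gaussian log-scale regression to one benchmark draw.

    The state-cell mean is log(sum_w exp(x beta)) over member strata with
    population weights w; coefficients are found by nonlinear least
    squares with an analytic Jacobian.
    """
    X, names = _design_matrix(strata, yll_rates, indicator_draw, covariates)
    M, keep = _state_aggregator(strata, geography, populations)
    coords = strata.coords()
    bench_vals = benchmark_draw.sel(
        state=list(geography.states), sex=coords["sex"],
        age=coords["age"], year=coords["year"],
    ).transpose("state", "sex", "age", "year").values
    y = np.log(np.maximum(bench_vals.ravel()[keep], 1e-12))

    def model_parts(beta):
        mu = np.exp(np.clip(X @ beta, -300, 40))
        agg = np.maximum(M @ mu, 1e-300)
        return mu, agg

    def resid(beta):
        _, agg = model_parts(beta)
        return np.log(agg) - y

    def jac(beta):
        mu, agg = model_parts(beta)
        # d log(agg_j) / d beta = (M_j . (mu * x)) / agg_j
        W = M @ sp.diags(mu)
        return (W @ X) / agg[:, None]

    # linearized warm start: log-linear regression on state-mean predictors
    Xbar = M @ X
    beta0, *_ = np.linalg.lstsq(Xbar, y, rcond=None)
    method = "lm" if y.size >= len(names) else "trf"
    res = least_squares(resid, beta0, jac=jac, method=method, xtol=1e-12)
    r = res.fun
    dof = max(r.size - len(names), 1)
    resid_var = float(r @ r) / dof
    J = jac(res.x)
    JtJ = J.T @ J
    cov = resid_var * np.linalg.pinv(JtJ)
    return YldModelFit(
        cause=cause,
        input_draw=input_draw,
        coef=res.x,
        coef_names=names,
        coef_cov=cov,
        resid_var=resid_var,
        n_obs=int(r.size),
    )


def propagate_draws(
    cause: str,
    inputs: YldInputs,
    cause_config: CauseConfig,
    seed: int,
) -> xr.DataArray:
    """Fit ``n_models`` models for one cause and simulate prediction draws.

    Model m consumes input draw m of each indicator cube and benchmark
    draw ``m * draws_per_model`` (the first draw of its lineage segment).
    Each model contributes ``draws_per_model`` prediction draws combining
    coefficient sampling (Gaussian at the fit) and residual noise; the
    output cube concatenates draws in (model, draw) order with lineage
    metadata recording the model of every draw.
    """
    nm, dpm = cause_config.n_models, cause_config.draws_per_model
    for name, cube in inputs.indicator_cubes.items():
        if cube.sizes[DRAW_DIM] < nm:
            raise ValueError(
                f"indicator {name!r} has {cube.sizes[DRAW_DIM]} draws, "
                f"fewer than n_models={nm}"
            )
    if inputs.benchmark.sizes[DRAW_DIM] < nm * dpm:
        raise ValueError("benchmark cube has fewer draws than required")
    strata = inputs.strata
    rng = np.random.default_rng(seed)
    out = np.empty((strata.n_strata, nm * dpm))
    X_template = None
    for m in range(nm):
        ind_draw = {
            name: cube.isel({DRAW_DIM: m})
            for name, cube in inputs.indicator_cubes.items()
        }
        bench = inputs.benchmark.isel({DRAW_DIM: m * dpm})
        fit = fit_cause_model(
            bench, inputs.yll, ind_draw, inputs.covariates,
            inputs.populations, strata, inputs.geography,
            cause=cause, input_draw=m,
        )
        X, _ = _design_matrix(strata, inputs.yll, ind_draw, inputs.covariates)
        try:
            Lc = np.linalg.cholesky(
                fit.coef_cov + 1e-12 * np.eye(len(fit.coef))
            )
        except np.linalg.LinAlgError:
            Lc = np.zeros((len(fit.coef), len(fit.coef)))
        betas = fit.coef[:, None] + Lc @ rng.standard_normal((len(fit.coef), dpm))
        eta = X @ betas  # (n_strata, dpm)
        if fit.resid_var > 0:
            eta = eta + rng.normal(
                0.0, np.sqrt(fit.resid_var), size=eta.shape
            )
        out[:, m * dpm:(m + 1) * dpm] = np.exp(np.clip(eta, -300, 40))
    dims = strata.dims + (DRAW_DIM,)
    coords = strata.coords()
    coords[DRAW_DIM] = np.arange(nm * dpm)
    da = xr.DataArray(
        out.reshape(strata.shape + (nm * dpm,)), dims=dims, coords=coords
    )
    return set_lineage(
        da,
        source=f"yld:{cause}",
        n_models=nm,
        draws_per_model=dpm,
        model_of_draw=np.repeat(np.arange(nm), dpm),
    )


def sum_causes(cause_cubes) -> xr.DataArray:
    """Element-wise draw-aligned sum of per-cause cubes, clipped to [0, 1].

    Accepts any iterable of cubes (so large per-cause cubes can be
    generated lazily and accumulated without stacking).  The number of
    clipped cells is logged, never silently discarded.
    """
    it = iter(cause_cubes)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("no cause cubes given") from None
    total = first.copy(deep=True)
    lineage = first.attrs.get("model_of_draw")
    n = 1
    for cube in it:
        require_aligned(total, cube)
        total = total + cube
        n += 1
    clipped = int((total.values > 1.0).sum() + (total.values < 0.0).sum())
    if clipped:
        logger.info(
            "all-cause YLD: clipped %d of %d cells to [0, 1]",
            clipped, total.size,
        )
    total = total.clip(0.0, 1.0)
    attrs = {"source": f"yld:all_cause({n})", "n_clipped": clipped}
    if lineage is not None:
        attrs["model_of_draw"] = lineage
        attrs["n_models"] = first.attrs.get("n_models")
        attrs["draws_per_model"] = first.attrs.get("draws_per_model")
    return set_lineage(total, **attrs)
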