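"""Hierarchical small-area prevalence models with structured random effects.

One model is fit per health indicator.  The linear predictor on the logit
scale combines a small fixed-effect design (intercept, county covariates,
age trend) with intrinsic random-effect blocks: ICAR over the county
adjacency graph, first-order random walks over year and age, and centered
exchangeable deviations over race (and education, when present).  Each
block has a single precision parameter.

Observations may refer to sets of strata; the binomial likelihood is
applied to k successes in n trials with success probability equal to the
population-weighted average of the member strata's prevalences
(:func:`aggregate_expectation`), so data reported at coarser aggregation
than the modelling targets enter the likelihood without information loss.

Inference follows the Laplace-approximate maximum marginal likelihood
strategy of TMB-style mixed models, re-implemented here: for candidate
block precisions, an inner Newton solve (with line search, so the joint
objective never decreases across accepted steps) locates the mode of fixed
plus random effects; the marginal likelihood of the precisions is the
joint density at the mode plus half the log-determinant ratio of prior to
curvature; the outer optimizer runs over log precisions.  Posterior draws
come from the Gaussian approximation at the mode with the curvature as
precision.

Sum-to-zero constraints on the intrinsic blocks are imposed softly: a
large fixed precision on each block's (per-component) sum keeps precision
matrices sparse and full rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import xarray as xr
from scipy.optimize import minimize
from scipy.special import expit

from .observations import IndicatorObservations
from .random_effects import (
    centered_iid_precision,
    icar_precision,
    rw1_precision,
)
from .strata import DRAW_DIM, StrataCoords, set_lineage
from .synthetic_data import Geography

logger = logging.getLogger(__name__)

_PBAR_EPS = 1e-12


def aggregate_expectation(p: np.ndarray, weights: np.ndarray) -> float:
    """Population-weighted average prevalence of a stratum set."""
    p = np.asarray(p, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("p and weights must align")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    return float(np.dot(p, w) / total)


# ---------------------------------------------------------------------------
# effect structure

@dataclass(frozen=True)
class RandomBlock:
    name: str
    size: int
    Q: sp.csr_matrix  # intrinsic structure precision (rows sum to zero)
    rank: int
    level_of_stratum: np.ndarray  # (n_strata,), int level codes
    offset: int  # first column of this block in the full design
    constraint_groups: tuple[tuple[int, ...], ...]  # soft sum-to-zero sets

    @property
    def sl(self) -> slice:
        return slice(self.offset, self.offset + self.size)


@dataclass
class EffectStructure:
    """Design matrices and prior precision blocks for one indicator model."""

    strata: StrataCoords
    fixed_names: tuple[str, ...]
    X: np.ndarray  # (n_strata, p_fixed)
    blocks: list[RandomBlock]
    constraint_precision: float = 1e4
    ridge_fixed: float = 1e-4
    A: sp.csr_matrix = field(init=False)

    def __post_init__(self) -> None:
        n = self.strata.n_strata
        parts = [sp.csr_matrix(self.X)]
        for b in self.blocks:
            Z = sp.csr_matrix(
                (np.ones(n), (np.arange(n), b.level_of_stratum)),
                shape=(n, b.size),
            )
            parts.append(Z)
        self.A = sp.hstack(parts).tocsr()

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_params(self) -> int:
        return self.n_fixed + sum(b.size for b in self.blocks)

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks)

    def prior_precision(self, log_tau: np.ndarray) -> np.ndarray:
        """Dense prior precision of (fixed, random) given log precisions."""
        p = self.n_params
        Q = np.zeros((p, p))
        Q[: self.n_fixed, : self.n_fixed] = self.ridge_fixed * np.eye(
            self.n_fixed
        )
        for tau_log, b in zip(log_tau, self.blocks):
            tau = float(np.exp(np.clip(tau_log, -30, 30)))
            Qb = tau * np.asarray(b.Q.todense())
            for group in b.constraint_groups:
                idx = np.asarray(group)
                Qb[np.ix_(idx, idx)] += self.constraint_precision / len(idx)
            Q[b.sl, b.sl] += Qb
        return Q

    def logdet_prior_varying(self, log_tau: np.ndarray) -> float:
        """The tau-dependent part of the prior log-normalizer (x2)."""
        return float(
            sum(b.rank * lt for b, lt in zip(self.blocks, log_tau))
        )


def build_effect_structure(
    geography: Geography,
    strata: StrataCoords,
    covariates: xr.DataArray | None = None,
    include_age_trend: bool = True,
    constraint_precision: float = 1e4,
    ridge_fixed: float = 1e-4,
) -> EffectStructure:
    """Assemble fixed design and sparse intrinsic precision blocks.

    Fixed effects: intercept, optionally a standardized age-midpoint trend,
    and any county-level covariates.  Random blocks: county ICAR (precision
    = degree minus adjacency), year RW1, age RW1 (second-difference
    penalties), race and education centered exchangeable.
    """
    missing = set(strata.counties) - set(geography.county_ids)
    if missing:
        raise ValueError(
            f"strata contain counties absent from the geography: "
            f"{sorted(missing)[:5]}"
        )
    idx = strata.index_arrays()
    n = strata.n_strata

    cols = [np.ones(n)]
    names = ["intercept"]
    if include_age_trend:
        mids = strata.age_grid.midpoints
        age_std = (mids - 40.0) / 25.0
        cols.append(age_std[idx["age"]])
        names.append("age_std")
    if covariates is not None:
        # align covariate county order with the strata county order
        cov = covariates.sel(county=list(strata.counties))
        for name in cov["covariate"].values:
            vals = cov.sel(covariate=name).values
            cols.append(vals[idx["county"]])
            names.append(str(name))
    X = np.column_stack(cols)

    geo_order = {c: i for i, c in enumerate(geography.county_ids)}
    county_map = np.array([geo_order[c] for c in strata.counties])
    comp = np.asarray(geography.components)

    blocks: list[RandomBlock] = []
    offset = X.shape[1]

    # county ICAR — strata counties index into the geography's graph
    Qc = icar_precision(geography.adjacency)
    ncomp = len(set(comp))
    groups = tuple(
        tuple(int(i) for i in np.flatnonzero(comp == c))
        for c in sorted(set(comp))
    )
    blocks.append(
        RandomBlock(
            "county", geography.n_counties, Qc,
            geography.n_counties - ncomp,
            county_map[idx["county"]], offset, groups,
        )
    )
    offset += geography.n_counties

    for dim, maker in (("year", rw1_precision), ("age", rw1_precision)):
        size = strata.shape[strata.dims.index(dim)]
        Q = maker(size)
        blocks.append(
            RandomBlock(
                dim, size, Q, max(size - 1, 0), idx[dim], offset,
                (tuple(range(size)),),
            )
        )
        offset += size

    exch_dims = [("race", len(strata.races))]
    if strata.educations:
        exch_dims.append(("education", len(strata.educations)))
    for dim, size in exch_dims:
        Q = centered_iid_precision(size)
        blocks.append(
            RandomBlock(
                dim, size, Q, max(size - 1, 0), idx[dim], offset,
                (tuple(range(size)),),
            )
        )
        offset += size

    return EffectStructure(
        strata=strata,
        fixed_names=tuple(names),
        X=X,
        blocks=blocks,
        constraint_precision=constraint_precision,
        ridge_fixed=ridge_fixed,
    )


# ---------------------------------------------------------------------------
# fitting

@dataclass(frozen=True)
class FitConfig:
    grad_tol: float = 1e-6
    max_inner: int = 100
    max_outer: int = 200
    init_log_tau: float = 2.0
    outer_fd_eps: float = 0.05  # finite-difference step for log precisions


@dataclass
class FittedModel:
    structure: EffectStructure
    indicator: str
    theta: np.ndarray
    log_tau: np.ndarray
    neg_hessian: np.ndarray
    grad_norm: float
    n_inner_iter: int
    n_outer_eval: int
    converged: bool
    laplace_loglik: float

    @property
    def fixed_effects(self) -> dict[str, float]:
        return dict(zip(self.structure.fixed_names, self.theta))

    def fixed_effect_se(self) -> dict[str, float]:
        cov = np.linalg.inv(self.neg_hessian)
        p = self.structure.n_fixed
        return dict(
            zip(self.structure.fixed_names, np.sqrt(np.diag(cov)[:p]))
        )


class _JointObjective:
    """Binomial likelihood on aggregated expectations plus Gaussian prior."""

    def __init__(self, obs: IndicatorObservations, structure: EffectStructure):
        self.A = structure.A
        self.Ad = structure.A.toarray()  # dense copy for BLAS Hessians
        self.M = obs.row_normalized()
        self.n = obs.n.astype(float)
        self.k = obs.k.astype(float)

    def value(self, theta: np.ndarray, Q: np.ndarray) -> float:
        pbar = self._pbar(theta)
        ll = float(
            np.sum(self.k * np.log(pbar) + (self.n - self.k) * np.log1p(-pbar))
        )
        return ll - 0.5 * float(theta @ Q @ theta)

    def _pbar(self, theta: np.ndarray) -> np.ndarray:
        p = expit(self.A @ theta)
        return np.clip(self.M @ p, _PBAR_EPS, 1 - _PBAR_EPS)

    def grad_hess(self, theta: np.ndarray, Q: np.ndarray):
        eta = self.A @ theta
        p = expit(eta)
        sprime = p * (1.0 - p)
        pbar = np.clip(self.M @ p, _PBAR_EPS, 1 - _PBAR_EPS)
        a = self.k / pbar - (self.n - self.k) / (1.0 - pbar)
        b = -self.k / pbar**2 - (self.n - self.k) / (1.0 - pbar) ** 2
        Mta = self.M.T @ a
        grad = self.A.T @ (sprime * Mta) - Q @ theta
        G = self.M.multiply(sprime).tocsr() @ self.Ad  # (n_obs, p) dense
        H1 = (G * b[:, None]).T @ G
        sdd = sprime * (1.0 - 2.0 * p)
        H2 = (self.Ad * (sdd * Mta)[:, None]).T @ self.Ad
        neg_hess = -(H1 + H2) + Q
        neg_hess_gn = -H1 + Q
        value = float(
            np.sum(self.k * np.log(pbar) + (self.n - self.k) * np.log1p(-pbar))
        ) - 0.5 * float(theta @ Q @ theta)
        return value, grad, neg_hess, neg_hess_gn


def _inner_newton(
    joint: _JointObjective,
    Q: np.ndarray,
    theta0: np.ndarray,
    cfg: FitConfig,
):
    """Maximize the joint objective over effects; monotone via line search."""
    theta = theta0.copy()
    value, grad, negH, negH_gn = joint.grad_hess(theta, Q)
    it = 0
    stalled = 0
    for it in range(1, cfg.max_inner + 1):
        gnorm = float(np.max(np.abs(grad)))
        if gnorm <= cfg.grad_tol:
            break
        step = None
        try:
            c, low = sla.cho_factor(negH, lower=True)
            step = sla.cho_solve((c, low), grad)
        except np.linalg.LinAlgError:
            pass
        if step is None or not np.all(np.isfinite(step)):
            c, low = sla.cho_factor(
                negH_gn + 1e-8 * np.eye(len(theta)), lower=True
            )
            step = sla.cho_solve((c, low), grad)
        # backtracking: accepted steps never decrease the objective
        t = 1.0
        for _ in range(40):
            cand = theta + t * step
            cand_val = joint.value(cand, Q)
            if np.isfinite(cand_val) and cand_val >= value - 1e-12:
                break
            t *= 0.5
        else:
            break
        improvement = cand_val - value
        theta = theta + t * step
        value, grad, negH, negH_gn = joint.grad_hess(theta, Q)
        # a stalled (linearly creeping) solve wastes outer-search time;
        # two consecutive negligible improvements end the inner loop and
        # the honest gradient norm is reported to the caller
        if improvement < 1e-9 * (1.0 + abs(value)):
            stalled += 1
            if stalled >= 2:
                break
        else:
            stalled = 0
    gnorm = float(np.max(np.abs(grad)))
    return theta, value, gnorm, negH, negH_gn, it


def _check_separable(obs: IndicatorObservations) -> bool:
    return bool(np.all(obs.k == 0) or np.all(obs.k == obs.n))


def fit_indicator_model(
    obs: IndicatorObservations,
    structure: EffectStructure,
    config: FitConfig = FitConfig(),
    fixed_log_tau: np.ndarray | None = None,
) -> FittedModel:
    """Maximize the Laplace-approximate marginal likelihood.

    ``fixed_log_tau`` pins the block log precisions (skipping the outer
    optimization), which is useful for degenerate-limit checks.
    """
    if _check_separable(obs):
        warnings.warn(
            f"indicator {obs.indicator!r}: separable data (all k=0 or all "
            "k=n); falling back to a ridge on the fixed effects",
            stacklevel=2,
        )
        structure.ridge_fixed = max(structure.ridge_fixed, 1e-2)

    joint = _JointObjective(obs, structure)
    n_blocks = len(structure.blocks)
    theta_warm = np.zeros(structure.n_params)
    pooled = float(np.clip(obs.k.sum() / obs.n.sum(), 1e-6, 1 - 1e-6))
    theta_warm[0] = np.log(pooled / (1 - pooled))  # intercept warm start
    state = {"theta": theta_warm, "inner_iters": 0, "evals": 0}

    def laplace(log_tau: np.ndarray) -> tuple[float, dict]:
        log_tau = np.clip(log_tau, -12.0, 12.0)
        Q = structure.prior_precision(log_tau)
        theta, value, gnorm, negH, negH_gn, its = _inner_newton(
            joint, Q, state["theta"], config
        )
        state["theta"] = theta
        state["inner_iters"] += its
        state["evals"] += 1
        try:
            c, _ = sla.cho_factor(negH, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        except np.linalg.LinAlgError:
            c, _ = sla.cho_factor(
                negH_gn + 1e-8 * np.eye(len(theta)), lower=True
            )
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            negH = negH_gn
        obj = (
            value
            + 0.5 * structure.logdet_prior_varying(log_tau)
            - 0.5 * logdet
        )
        return obj, {
            "theta": theta, "gnorm": gnorm, "negH": negH, "value": value,
        }

    if fixed_log_tau is not None:
        log_tau = np.asarray(fixed_log_tau, dtype=float)
        obj, info = laplace(log_tau)
    else:
        x0 = np.full(n_blocks, config.init_log_tau)

        def neg_obj(x):
            return -laplace(x)[0]

        res = minimize(
            neg_obj,
            x0,
            method="L-BFGS-B",
            bounds=[(-12.0, 12.0)] * n_blocks,
            options={
                "maxiter": config.max_outer,
                "eps": config.outer_fd_eps,
                "ftol": 1e-10,
                "gtol": 1e-3,
            },
        )
        log_tau = np.clip(res.x, -12.0, 12.0)
        obj, info = laplace(log_tau)

    converged = info["gnorm"] <= max(config.grad_tol, 1e-5)
    if not converged:
        warnings.warn(
            f"indicator {obs.indicator!r}: inner gradient norm "
            f"{info['gnorm']:.2e} above tolerance after fitting",
            stacklevel=2,
        )
    logger.info(
        "fit %s: laplace=%.3f log_tau=%s grad=%.2e (%d outer evals)",
        obs.indicator, obj, np.round(log_tau, 2), info["gnorm"],
        state["evals"],
    )
    return FittedModel(
        structure=structure,
        indicator=obs.indicator,
        theta=info["theta"],
        log_tau=log_tau,
        neg_hessian=info["negH"],
        grad_norm=info["gnorm"],
        n_inner_iter=state["inner_iters"],
        n_outer_eval=state["evals"],
        converged=converged,
        laplace_loglik=obj,
    )


# ---------------------------------------------------------------------------
# posterior draws

def _name_offending_block(structure: EffectStructure, negH: np.ndarray) -> str:
    evals, evecs = np.linalg.eigh(negH)
    v = np.abs(evecs[:, 0])
    if np.argmax(v) < structure.n_fixed:
        return "fixed"
    for b in structure.blocks:
        if b.offset <= int(np.argmax(v)) < b.offset + b.size:
            return b.name
    return "unknown"


def draw_posterior(
    fitted: FittedModel,
    structure: EffectStructure,
    n_draws: int,
    seed: int,
    education_weights: np.ndarray | None = None,
) -> xr.DataArray:
    """Sample prevalence draws from the Gaussian approximation at the mode.

    Effects are drawn from N(mode, curvature^{-1}), pushed through the
    design and the inverse logit; when the strata carry an education axis
    it is marginalized out with the given weights (uniform by default),
    since downstream strata have no education dimension.
    """
    negH = fitted.neg_hessian
    try:
        L = sla.cholesky(negH, lower=True)
    except np.linalg.LinAlgError as err:
        block = _name_offending_block(structure, negH)
        raise ValueError(
            f"curvature is not positive definite (block {block!r})"
        ) from err
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(fitted.theta), n_draws))
    thetas = fitted.theta[:, None] + sla.solve_triangular(
        L, z, lower=True, trans="T"
    )
    p = expit(structure.A @ thetas)  # (n_strata, n_draws)
    strata = structure.strata
    cube = p.reshape(strata.shape + (n_draws,))
    dims = strata.dims + (DRAW_DIM,)
    coords = strata.coords()
    coords[DRAW_DIM] = np.arange(n_draws)
    da = xr.DataArray(cube, dims=dims, coords=coords)
    if strata.educations:
        n_edu = len(strata.educations)
        w = (
            np.full(n_edu, 1.0 / n_edu)
            if education_weights is None
            else np.asarray(education_weights, dtype=float)
        )
        w = w / w.sum()
        da = (da * xr.DataArray(w, dims=("education",))).sum("education")
    return set_lineage(da, source=f"indicator:{fitted.indicator}")
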