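"""Synthetic inputs with known ground truth for the full HALE pipeline.

No raw survey or burden microdata ship with this project, so every input
the pipeline consumes is generated here: a merged-county geography as an
abstract adjacency graph, populations per stratum, county sociodemographic
covariates, true prevalence surfaces per health indicator, true
cause-specific YLL and YLD rate surfaces, state-level YLD benchmarks,
survey-style binomial indicator observations at mixed aggregation levels,
and abridged life tables.  The generating model mirrors the estimator's
assumptions — logit/log-linear fixed effects plus ICAR county, RW1 year,
RW1 age, and exchangeable race random fields — so that downstream stages
have a recoverable truth.

Default scale: 48 counties in 4 states, 2 races, 2 sexes, abridged ages
[0,1), [1,5), 5-year groups to [85,inf), years 2009-2019.  This keeps an
end-to-end run within minutes on a single core while retaining every
structural feature of the estimation problem (spatial adjacency, mixed
aggregation, draw bookkeeping, small populations that trigger masking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xarray as xr
from scipy.sparse.csgraph import connected_components

from .observations import IndicatorObservations
from .random_effects import (
    centered_iid_precision,
    icar_precision,
    rw1_precision,
    sample_intrinsic,
)
from .strata import (
    DEFAULT_AGE_STARTS,
    RACE_LABELS,
    SEX_LABELS,
    AgeGrid,
    StrataCoords,
)
from .sullivan_hale import lifetable_from_mx

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# geography

@dataclass(frozen=True)
class Geography:
    """Counties on an abstract adjacency graph, partitioned into states."""

    county_ids: tuple[str, ...]
    adjacency: sp.csr_matrix
    state_of: tuple[str, ...]
    components: tuple[int, ...]

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def states(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.state_of:
            seen.setdefault(s, None)
        return tuple(seen)

    @property
    def state_codes(self) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.states)}
        return np.array([lookup[s] for s in self.state_of])

    def neighbors(self, county: str) -> tuple[str, ...]:
        i = self.county_ids.index(county)
        row = self.adjacency.getrow(i)
        return tuple(self.county_ids[j] for j in row.indices)


def make_geography(
    n_counties: int,
    n_states: int,
    seed: int = 0,
    rewire_fraction: float = 0.0,
) -> Geography:
    """Lay counties on a near-square lattice with 4-neighbor adjacency.

    States are contiguous, near-equal chunks of the row-major county order.
    ``rewire_fraction`` optionally replaces that share of lattice edges
    with random non-adjacent pairs (keeping the graph symmetric).
    """
    if n_states < 1 or n_counties < n_states:
        raise ValueError("need n_counties >= n_states >= 1")
    ncols = int(np.ceil(np.sqrt(n_counties)))
    rows, cols = np.divmod(np.arange(n_counties), ncols)
    edges = set()
    for i in range(n_counties):
        for dr, dc in ((0, 1), (1, 0)):
            r, c = rows[i] + dr, cols[i] + dc
            j = r * ncols + c
            if c < ncols and j < n_counties and r <= rows.max():
                edges.add((i, j))
    edges = sorted(edges)
    if rewire_fraction > 0 and n_counties > 3:
        rng = np.random.default_rng(seed)
        n_rewire = int(round(rewire_fraction * len(edges)))
        for idx in rng.choice(len(edges), size=n_rewire, replace=False):
            a = int(rng.integers(n_counties))
            b = int(rng.integers(n_counties))
            if a != b:
                edges[idx] = (min(a, b), max(a, b))
    edges = sorted(set(edges))
    if edges:
        r, c = zip(*edges)
        data = np.ones(len(edges))
        A = sp.coo_matrix((data, (r, c)), shape=(n_counties, n_counties))
        A = ((A + A.T) > 0).astype(float).tocsr()
        A.setdiag(0)
        A.eliminate_zeros()
    else:
        A = sp.csr_matrix((n_counties, n_counties))
    bounds = np.linspace(0, n_counties, n_states + 1).round().astype(int)
    state_of = np.empty(n_counties, dtype=object)
    for s in range(n_states):
        state_of[bounds[s]:bounds[s + 1]] = f"s{s:02d}"
    _, comp = connected_components(A, directed=False)
    width = max(3, len(str(n_counties - 1)))
    ids = tuple(f"c{i:0{width}d}" for i in range(n_counties))
    return Geography(ids, A, tuple(state_of), tuple(int(x) for x in comp))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class EffectVariances:
    """Random-effect variances on the link scale, by block."""

    county: float = 0.0
    year: float = 0.0
    age: float = 0.0
    race: float = 0.0
    education: float = 0.0
    residual: float = 0.0

    def __post_init__(self) -> None:
        for name in ("county", "year", "age", "race", "education", "residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative variance for block {name!r}")


#: baseline log-mortality age schedule (per person-year), one value per
#: default age group — an idealised low-mortality national pattern giving
#: life expectancy at birth near 80 years.
BASELINE_MX = (
    0.0055, 0.00028, 0.00015, 0.00018, 0.00060, 0.00090, 0.00110, 0.00135,
    0.00170, 0.00230, 0.00340, 0.00500, 0.00750, 0.01100, 0.01700, 0.02700,
    0.04400, 0.07500, 0.15000,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_counties: int = 48
    n_states: int = 4
    n_races: int = 2
    age_starts: tuple[float, ...] = DEFAULT_AGE_STARTS
    years: tuple[int, ...] = tuple(range(2009, 2020))
    n_education: int = 1
    indicators: tuple[str, ...] = ("activity_limit", "asthma", "fair_health")
    n_causes: int = 16
    covariates: tuple[str, ...] = ("poverty", "college")
    rewire_fraction: float = 0.0

    # fixed effects on the logit scale for each indicator:
    # intercept, coefficient on standardized age midpoint, then one
    # coefficient per sociodemographic covariate
    indicator_intercepts: tuple[float, ...] = (-1.6, -2.0, -1.2)
    indicator_age_slopes: tuple[float, ...] = (0.9, 0.3, 0.6)
    indicator_cov_coefs: tuple[tuple[float, ...], ...] = (
        (0.40, -0.30), (0.15, -0.10), (0.50, -0.40),
    )

    prevalence_variances: EffectVariances = field(
        default_factory=lambda: EffectVariances(
            county=0.040, year=0.002, age=0.010, race=0.020
        )
    )
    mortality_variances: EffectVariances = field(
        default_factory=lambda: EffectVariances(
            county=0.010, year=0.0005, age=0.0, race=0.010
        )
    )
    yld_variances: EffectVariances = field(
        default_factory=lambda: EffectVariances(
            county=0.005, year=0.0002, age=0.0, race=0.002
        )
    )

    # YLD truth: log yld_c = age_base_c(age) + b1_c log YLL_c + b2_c
    # prevalence of the first indicator + b3_c first covariate + random
    # fields.  The age-base offsets anchor the all-cause rate to a
    # realistic profile (a few percent in childhood rising to ~0.4 in the
    # oldest group) while the YLL term carries cross-stratum correlation;
    # b1 for the first cause is 0.8, the rest cycle moderate values.
    yld_log_yll_coefs: tuple[float, ...] = ()
    yld_indicator_coef: float = 0.6
    yld_covariate_coef: float = 0.1
    #: all-cause YLD age profile: floor + span * logistic((age - mid)/scale)
    yld_profile_floor: float = 0.04
    yld_profile_span: float = 0.40
    yld_profile_midage: float = 55.0
    yld_profile_scale: float = 20.0

    # mortality year drift (log scale per decade) — slight worsening
    mortality_trend: float = 0.02

    def __post_init__(self) -> None:
        if not (1 <= self.n_races <= len(RACE_LABELS)):
            raise ValueError("n_races must be between 1 and 5")
        if self.n_counties < self.n_states:
            raise ValueError("need n_counties >= n_states")
        if len(self.age_starts) == len(DEFAULT_AGE_STARTS):
            pass  # baseline schedule aligns
        if not self.yld_log_yll_coefs:
            coefs = [0.8] + [
                0.3 + 0.5 * ((i * 7) % 10) / 10.0
                for i in range(1, self.n_causes)
            ]
            object.__setattr__(self, "yld_log_yll_coefs", tuple(coefs))
        if len(self.yld_log_yll_coefs) != self.n_causes:
            raise ValueError("one log-YLL coefficient per cause required")

    @property
    def races(self) -> tuple[str, ...]:
        return RACE_LABELS[: self.n_races]

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(f"cause_{i + 1:02d}" for i in range(self.n_causes))

    @property
    def educations(self) -> tuple[str, ...]:
        if self.n_education <= 1:
            return ()
        return tuple(f"edu_{i + 1}" for i in range(self.n_education))

    @property
    def age_grid(self) -> AgeGrid:
        return AgeGrid(self.age_starts)

    def strata_for(self, geography: Geography, education: bool = False) -> StrataCoords:
        return StrataCoords(
            counties=geography.county_ids,
            races=self.races,
            sexes=SEX_LABELS,
            age_grid=self.age_grid,
            years=self.years,
            educations=self.educations if education else (),
        )

    def baseline_mx(self) -> np.ndarray:
        if len(self.age_starts) == len(BASELINE_MX):
            return np.asarray(BASELINE_MX)
        # interpolate the baseline schedule onto a non-default grid
        ref = AgeGrid(DEFAULT_AGE_STARTS)
        return np.exp(
            np.interp(
                self.age_grid.midpoints, ref.midpoints, np.log(BASELINE_MX)
            )
        )


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """True surfaces plus the effects and coefficients that generated them."""

    config: SyntheticConfig
    geography: Geography
    covariates: xr.DataArray  # (covariate, county)
    prevalence: dict[str, xr.DataArray]  # indicator -> stratum surface
    yll: dict[str, xr.DataArray]  # cause -> stratum surface
    yld: dict[str, xr.DataArray]  # cause -> stratum surface
    mx: xr.DataArray
    coefficients: dict[str, dict[str, float | np.ndarray]]
    fields: dict[str, dict[str, np.ndarray]]

    @property
    def all_cause_yld(self) -> xr.DataArray:
        total = sum(self.yld.values())
        return total.clip(0.0, 1.0)


def _standardized_age(age_grid: AgeGrid) -> np.ndarray:
    mids = age_grid.midpoints
    return (mids - 40.0) / 25.0


def _sample_fields(
    geography: Geography,
    config: SyntheticConfig,
    variances: EffectVariances,
    rng: np.random.Generator,
    educations: int = 0,
) -> dict[str, np.ndarray]:
    """One realization of each random-effect block on the link scale."""
    Qc = icar_precision(geography.adjacency)
    fields = {
        "county": sample_intrinsic(Qc, variances.county, rng)[0],
        "year": sample_intrinsic(
            rw1_precision(len(config.years)), variances.year, rng
        )[0],
        "age": sample_intrinsic(
            rw1_precision(config.age_grid.n_groups), variances.age, rng
        )[0],
        "race": sample_intrinsic(
            centered_iid_precision(config.n_races), variances.race, rng
        )[0],
    }
    if educations > 1:
        fields["education"] = sample_intrinsic(
            centered_iid_precision(educations), variances.education, rng
        )[0]
    return fields


def _field_surface(
    coords: StrataCoords, fields: dict[str, np.ndarray]
) -> np.ndarray:
    """Broadcast additive main-effect fields onto the full stratum grid."""
    shape = coords.shape
    dims = coords.dims
    out = np.zeros(shape)
    for name, values in fields.items():
        if name == "residual":
            continue
        ax = dims.index(name)
        view = [1] * len(shape)
        view[ax] = shape[ax]
        out = out + np.asarray(values).reshape(view)
    return out


def simulate_covariates(
    geography: Geography, config: SyntheticConfig, seed: int
) -> xr.DataArray:
    """County-level sociodemographic covariates, spatially smooth.

    Each covariate is a standardized ICAR field plus white noise, mimicking
    e.g. poverty or college-attainment shares on the probit scale.
    """
    rng = np.random.default_rng(seed)
    Q = icar_precision(geography.adjacency)
    rows = []
    for _ in config.covariates:
        f = sample_intrinsic(Q, 1.0, rng)[0] if geography.n_counties > 1 else (
            np.zeros(1)
        )
        f = f + 0.3 * rng.standard_normal(geography.n_counties)
        sd = f.std()
        rows.append(f / sd if sd > 0 else f)
    return xr.DataArray(
        np.array(rows),
        dims=("covariate", "county"),
        coords={
            "covariate": list(config.covariates),
            "county": list(geography.county_ids),
        },
    )


def simulate_truth(
    geography: Geography, config: SyntheticConfig, seed: int
) -> GroundTruth:
    """Generate every true surface.

    Child random streams are spawned from the master seed in a fixed
    documented order: covariates, mortality, YLL, one per indicator, one
    per cause (YLD fields), so adding surfaces never perturbs earlier ones.
    """
    ss = np.random.SeedSequence(seed)
    n_streams = 3 + len(config.indicators) + config.n_causes
    children = ss.spawn(n_streams)
    it = iter(children)
    covariates = simulate_covariates(geography, config, next(it))

    coords = config.strata_for(geography)
    coords_edu = config.strata_for(geography, education=True)
    age_std = _standardized_age(config.age_grid)
    dims = coords.dims
    nage_ax = dims.index("age")

    def bcast(vec: np.ndarray, dim: str, c: StrataCoords) -> np.ndarray:
        view = [1] * len(c.dims)
        view[c.dims.index(dim)] = len(vec)
        return np.asarray(vec).reshape(view)

    coefficients: dict[str, dict] = {}
    all_fields: dict[str, dict[str, np.ndarray]] = {}

    # --- mortality ---------------------------------------------------------
    rng_m = np.random.default_rng(next(it))
    f_m = _sample_fields(geography, config, config.mortality_variances, rng_m)
    trend = config.mortality_trend * (
        (np.asarray(config.years) - np.mean(config.years)) / 10.0
    )
    log_mx = (
        np.log(config.baseline_mx()).reshape(
            [config.age_grid.n_groups if d == "age" else 1 for d in dims]
        )
        + _field_surface(coords, f_m)
        + bcast(trend, "year", coords)
    )
    if config.mortality_variances.residual > 0:
        log_mx = log_mx + rng_m.normal(
            0.0, np.sqrt(config.mortality_variances.residual), coords.shape
        )
    mx = coords.from_flat(np.exp(log_mx).ravel())
    all_fields["mortality"] = f_m
    coefficients["mortality"] = {
        "baseline_log_mx": np.log(config.baseline_mx()),
        "trend": config.mortality_trend,
    }

    # --- YLL rates per cause ----------------------------------------------
    rng_y = np.random.default_rng(next(it))
    shares = np.linspace(1.5, 0.5, config.n_causes)
    shares = shares / shares.sum()
    yll: dict[str, xr.DataArray] = {}
    for c_i, cause in enumerate(config.causes):
        jitter = 0.1 * rng_y.standard_normal(geography.n_counties)
        log_yll = (
            np.log(mx.values * shares[c_i] * 25.0)
            + bcast(jitter, "county", coords)
        )
        yll[cause] = coords.from_flat(np.exp(log_yll).ravel())
    coefficients["yll"] = {"shares": shares, "years_lost": 25.0}

    # --- indicator prevalence ---------------------------------------------
    prevalence: dict[str, xr.DataArray] = {}
    cov_vals = covariates.values  # (n_cov, n_county)
    for i, ind in enumerate(config.indicators):
        rng_i = np.random.default_rng(next(it))
        f = _sample_fields(
            geography,
            config,
            config.prevalence_variances,
            rng_i,
            educations=config.n_education,
        )
        c = coords_edu
        eta = (
            config.indicator_intercepts[i]
            + config.indicator_age_slopes[i] * bcast(age_std, "age", c)
            + _field_surface(c, f)
        )
        for j in range(len(config.covariates)):
            eta = eta + config.indicator_cov_coefs[i][j] * bcast(
                cov_vals[j], "county", c
            )
        if config.prevalence_variances.residual > 0:
            eta = eta + rng_i.normal(
                0.0, np.sqrt(config.prevalence_variances.residual), c.shape
            )
        prevalence[ind] = c.from_flat(_expit(eta).ravel())
        all_fields[f"prevalence:{ind}"] = f
        coefficients[f"prevalence:{ind}"] = {
            "intercept": config.indicator_intercepts[i],
            "age_slope": config.indicator_age_slopes[i],
            "covariates": np.asarray(config.indicator_cov_coefs[i]),
        }

    # --- YLD rates per cause ----------------------------------------------
    first_ind = config.indicators[0]
    p_first = prevalence[first_ind]
    if "education" in p_first.dims:
        p_first = p_first.mean("education")
    from scipy.special import expit as _sigmoid

    profile = config.yld_profile_floor + config.yld_profile_span * _sigmoid(
        (config.age_grid.midpoints - config.yld_profile_midage)
        / config.yld_profile_scale
    )
    age_axes = tuple(i for i, d in enumerate(dims) if d != "age")
    yld: dict[str, xr.DataArray] = {}
    for c_i, cause in enumerate(config.causes):
        rng_c = np.random.default_rng(next(it))
        f = _sample_fields(geography, config, config.yld_variances, rng_c)
        b1 = config.yld_log_yll_coefs[c_i]
        eta = (
            b1 * np.log(yll[config.causes[c_i]].values)
            + config.yld_indicator_coef * p_first.values
            + config.yld_covariate_coef * bcast(cov_vals[0], "county", coords)
            + _field_surface(coords, f)
        )
        # anchor the cause's age profile: the per-age mean of exp(eta)
        # equals the target share of the all-cause profile exactly
        target_c = profile * shares[c_i]
        age_mean = np.log(np.exp(eta).mean(axis=age_axes))
        age_base = np.log(target_c) - age_mean
        surface = np.clip(
            np.exp(eta + bcast(age_base, "age", coords)), 0.0, 1.0
        )
        yld[cause] = coords.from_flat(surface.ravel())
        all_fields[f"yld:{cause}"] = f
        coefficients[f"yld:{cause}"] = {
            "age_base": age_base,
            "log_yll": b1,
            "indicator": config.yld_indicator_coef,
            "covariate": config.yld_covariate_coef,
        }

    return GroundTruth(
        config=config,
        geography=geography,
        covariates=covariates,
        prevalence=prevalence,
        yll=yll,
        yld=yld,
        mx=mx,
        coefficients=coefficients,
        fields=all_fields,
    )


def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


# ---------------------------------------------------------------------------
# populations

def simulate_population(
    geography: Geography, config: SyntheticConfig, seed: int
) -> xr.DataArray:
    """Person-counts per stratum with realistic skew.

    County totals are lognormal (median ~15 000, heavy right tail); the
    first race listed takes a minority share per county so that small
    county-by-race populations (the masking case) occur naturally.  Age
    structure decays smoothly; sexes split 51/49; totals drift +0.5%/year.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    n_c = geography.n_counties
    county_total = np.exp(rng.normal(np.log(15_000.0), 1.1, n_c))
    shares = np.empty((n_c, config.n_races))
    if config.n_races == 1:
        shares[:] = 1.0
    else:
        minority = rng.beta(1.6, 5.0, size=(n_c, config.n_races - 1))
        minority = minority / config.n_races  # keep minority shares modest
        shares[:, :-1] = minority
        shares[:, -1] = 1.0 - minority.sum(axis=1)
    age_w = np.exp(-0.018 * config.age_grid.midpoints)
    age_w = age_w / age_w.sum()
    sex_w = np.array([0.51, 0.49])
    yr = np.asarray(config.years)
    growth = (1.005) ** (yr - yr[0])
    pop = (
        county_total[:, None, None, None, None]
        * shares[:, :, None, None, None]
        * sex_w[None, None, :, None, None]
        * age_w[None, None, None, :, None]
        * growth[None, None, None, None, :]
    )
    coords = config.strata_for(geography)
    return coords.from_flat(pop.ravel())


# ---------------------------------------------------------------------------
# indicator observations

@dataclass(frozen=True)
class ObservationDesign:
    """Which observations are fine-stratum and which are aggregated.

    With probability ``aggregate_fraction`` a (race, sex, age, year) cell
    is observed only as state-level aggregates (one observation per state,
    pooling that state's counties with population weights); otherwise one
    fine observation per county is emitted.  When an education axis exists,
    observations always pool education levels with population weights,
    mirroring surveys that do not report education.
    """

    n_per_obs: int = 1000
    aggregate_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_per_obs < 0:
            raise ValueError("n_per_obs must be non-negative")
        if not 0.0 <= self.aggregate_fraction <= 1.0:
            raise ValueError("aggregate_fraction must lie in [0, 1]")


def aggregate_prevalence(p: np.ndarray, weights: np.ndarray) -> float:
    """Population-weighted mean prevalence of a stratum set."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty stratum set")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("stratum-set weights must sum to a positive value")
    return float(np.dot(np.asarray(p, dtype=float), w) / tot)


def simulate_indicator_observations(
    truth: GroundTruth,
    populations: xr.DataArray,
    design: ObservationDesign,
    seed: int,
) -> dict[str, IndicatorObservations]:
    """Binomial observations per indicator at mixed aggregation levels.

    Successes are drawn k ~ Binomial(n, p-bar) with p-bar the
    population-weighted mean of true prevalence over the observation's
    stratum set.  Rows with n = 0 are never emitted.
    """
    if design.n_per_obs == 0:
        raise ValueError("n_per_obs = 0 would emit empty observations")
    config = truth.config
    geography = truth.geography
    coords = config.strata_for(geography, education=True)
    dims = coords.dims
    shape = coords.shape
    n_edu = max(1, len(config.educations))
    pop = populations.values  # (county, race, sex, age, year)
    # spread population uniformly over education levels if present
    state_codes = geography.state_codes
    n_states = len(geography.states)

    ss = np.random.SeedSequence([seed, 29])
    out: dict[str, IndicatorObservations] = {}
    cell_shape = (
        len(config.races),
        len(SEX_LABELS),
        config.age_grid.n_groups,
        len(config.years),
    )
    strides = np.array(
        [int(np.prod(shape[k + 1:])) for k in range(len(shape))]
    )

    for ind_i, ind in enumerate(config.indicators):
        rng = np.random.default_rng(ss.spawn(1)[0])
        p_true = truth.prevalence[ind].values  # includes education axis if any
        agg_cell = rng.random(cell_shape) < design.aggregate_fraction
        rows_i: list[int] = []
        cols_i: list[int] = []
        w_data: list[float] = []
        ns: list[int] = []
        ks: list[int] = []
        levels: list[str] = []
        obs_row = 0

        def flat_index(c, r, s, a, y, e):
            idx = (
                c * strides[0] + r * strides[1] + s * strides[2]
                + a * strides[3] + y * strides[4]
            )
            if len(shape) == 6:
                idx += e * strides[5]
            return idx

        for r in range(cell_shape[0]):
            for s in range(cell_shape[1]):
                for a in range(cell_shape[2]):
                    for y in range(cell_shape[3]):
                        if agg_cell[r, s, a, y]:
                            groups = [
                                np.flatnonzero(state_codes == st)
                                for st in range(n_states)
                            ]
                        else:
                            groups = [
                                np.array([c])
                                for c in range(geography.n_counties)
                            ]
                        for members in groups:
                            cols, w, pvals = [], [], []
                            for c in members:
                                base_w = pop[c, r, s, a, y] / n_edu
                                for e in range(n_edu):
                                    cols.append(flat_index(c, r, s, a, y, e))
                                    w.append(base_w)
                            pvals = p_true.ravel()[cols]
                            pbar = aggregate_prevalence(pvals, w)
                            k = int(rng.binomial(design.n_per_obs, pbar))
                            rows_i.extend([obs_row] * len(cols))
                            cols_i.extend(cols)
                            w_data.extend(w)
                            ns.append(design.n_per_obs)
                            ks.append(k)
                            levels.append(
                                "state" if agg_cell[r, s, a, y] else "county"
                            )
                            obs_row += 1
        M = sp.coo_matrix(
            (w_data, (rows_i, cols_i)), shape=(obs_row, coords.n_strata)
        ).tocsr()
        meta = pd.DataFrame(
            {"obs_id": [f"{ind}_{j:06d}" for j in range(obs_row)],
             "level": levels}
        )
        out[ind] = IndicatorObservations(
            indicator=ind,
            strata=coords,
            n=np.asarray(ns),
            k=np.asarray(ks),
            membership=M,
            meta=meta,
        )
        logger.info(
            "indicator %s: %d observations (%d state-aggregated cells)",
            ind, obs_row, int(agg_cell.sum()),
        )
    return out


# ---------------------------------------------------------------------------
# benchmarks and life tables

def simulate_benchmarks(
    truth: GroundTruth,
    populations: xr.DataArray,
    n_draws: int = 1000,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> dict[str, xr.DataArray]:
    """State-level YLD-rate benchmarks per cause, sex, age, year, and draw.

    The benchmark is the population-weighted mean of the true county-race
    YLD rates over each state, optionally with lognormal noise per draw
    (noise_sd = 0 makes every draw equal the weighted mean exactly).
    """
    geography = truth.geography
    config = truth.config
    codes = geography.state_codes
    n_states = len(geography.states)
    pop = populations.values  # (county, race, sex, age, year)
    den = np.zeros((n_states,) + pop.shape[2:])
    np.add.at(den, codes, pop.sum(axis=1))
    if np.any(den <= 0):
        raise ValueError("zero total population in a state-age-sex-year cell")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 43]))
    out: dict[str, xr.DataArray] = {}
    for cause in config.causes:
        rate = truth.yld[cause].values
        num = np.zeros_like(den)
        np.add.at(num, codes, (pop * rate).sum(axis=1))
        wmean = num / den  # (state, sex, age, year)
        if noise_sd > 0:
            noise = np.exp(
                rng.normal(0.0, noise_sd, wmean.shape + (n_draws,))
            )
        else:
            noise = np.ones(wmean.shape + (n_draws,))
        draws = wmean[..., None] * noise
        out[cause] = xr.DataArray(
            draws,
            dims=("state", "sex", "age", "year", "draw"),
            coords={
                "state": list(geography.states),
                "sex": list(SEX_LABELS),
                "age": list(config.age_grid.labels),
                "year": list(config.years),
                "draw": np.arange(n_draws),
            },
        )
        if not np.all(np.isfinite(draws)) or np.any(draws < 0):
            raise AssertionError("benchmark draws must be finite and >= 0")
    return out


def simulate_life_tables(truth: GroundTruth, a0_infant: float = 0.2):
    """Abridged life tables per stratum, deterministic given the truth."""
    return lifetable_from_mx(truth.mx, truth.config.age_grid, a0_infant=a0_infant)
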