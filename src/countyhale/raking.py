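"""Multiplicative raking of county-race YLD rates to state benchmarks.

For every (state, sex, age, year, draw) cell, all member county-race
estimates are scaled by a common factor so their population-weighted
average equals the benchmark exactly:

    factor = benchmark / weighted_mean(estimates)

Raking is multiplicative because rates are positive; it preserves the
within-state rank order of strata and is idempotent.  Because YLD rates
are bounded by 1 (full-time disability per person-year), any value pushed
above 1 is clipped and the remaining strata are re-raked so the benchmark
constraint still holds exactly; the clip-and-rerake loop converges in a
handful of passes and errors out (naming the cell) if it cannot.
"""

from __future__ import annotations

import logging

import numpy as np
import xarray as xr

from .strata import DRAW_DIM, set_lineage
from .synthetic_data import Geography

logger = logging.getLogger(__name__)

_TOL = 1e-10
_MAX_PASSES = 50


def raking_factor(
    estimates: np.ndarray, weights: np.ndarray, benchmark: float
) -> float:
    """The scalar factor aligning a weighted mean with its benchmark."""
    w = np.asarray(weights, dtype=float)
    x = np.asarray(estimates, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    wmean = float(np.dot(w, x) / total)
    if wmean <= 0:
        if benchmark == 0:
            return 1.0
        raise ValueError("cannot rake: weighted mean of estimates is zero")
    return float(benchmark) / wmean


def apply_raking(
    cube: xr.DataArray,
    populations: xr.DataArray,
    geography: Geography,
    benchmarks: xr.DataArray,
    upper_bound: float = 1.0,
) -> xr.DataArray:
    """Rake a stratum draw cube to state benchmarks, cell by cell.

    ``cube`` has dims (county, race, sex, age, year, draw); ``benchmarks``
    has dims (state, sex, age, year, draw) aligned on draw index.  The
    post-condition |weighted mean - benchmark| <= 1e-10 * benchmark is
    asserted for every cell before returning.
    """
    cube = cube.transpose("county", "race", "sex", "age", "year", DRAW_DIM)
    bench = benchmarks.transpose("state", "sex", "age", "year", DRAW_DIM)
    if list(bench["state"].values) != list(geography.states):
        bench = bench.sel(state=list(geography.states))
    if bench.sizes[DRAW_DIM] != cube.sizes[DRAW_DIM]:
        raise ValueError(
            "benchmark and cube draw counts differ; raking is draw-aligned"
        )
    codes = geography.state_codes
    n_states = len(geography.states)
    V = cube.values.copy()  # (county, race, sex, age, year, draw)
    P = populations.transpose("county", "race", "sex", "age", "year").values
    B = bench.values  # (state, sex, age, year, draw)

    den = np.zeros((n_states,) + P.shape[2:])
    np.add.at(den, codes, P.sum(axis=1))
    if np.any(den <= 0):
        raise ValueError("a state cell has zero total population")

    PW = P[..., None]  # broadcast weights over draws
    active = np.ones_like(V, dtype=bool)  # strata still free to scale
    for pass_no in range(_MAX_PASSES):
        num = np.zeros((n_states,) + V.shape[2:])
        np.add.at(num, codes, np.where(active, PW * V, 0.0).sum(axis=1))
        fixed_mass = np.zeros_like(num)
        np.add.at(
            fixed_mass, codes, np.where(~active, PW * V, 0.0).sum(axis=1)
        )
        target = B * den[..., None] - fixed_mass
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(num > 0, target / np.maximum(num, 1e-300), 1.0)
        if np.any(target < -1e-9):
            cell = np.argwhere(target < -1e-9)[0]
            raise ValueError(
                "raking cannot meet the benchmark after clipping in cell "
                f"(state={geography.states[cell[0]]}, sex_i={cell[1]}, "
                f"age_i={cell[2]}, year_i={cell[3]}, draw={cell[4]})"
            )
        V = np.where(active, V * factor[codes][:, None], V)
        over = V > upper_bound
        if not over.any():
            break
        V = np.where(over, upper_bound, V)
        active &= ~over
        if pass_no == _MAX_PASSES - 1:
            raise ValueError("clip-and-rerake loop failed to converge")

    # post-condition: recomputed weighted means equal benchmarks
    num = np.zeros((n_states,) + V.shape[2:])
    np.add.at(num, codes, (PW * V).sum(axis=1))
    wmean = num / den[..., None]
    gap = np.abs(wmean - B)
    if np.any(gap > _TOL * np.maximum(B, 1e-12)):
        worst = np.argwhere(gap > _TOL * np.maximum(B, 1e-12))[0]
        raise AssertionError(
            f"raking post-condition violated at cell {tuple(worst)}"
        )

    # raking report: largest departure from unity per state and year
    with np.errstate(divide="ignore", invalid="ignore"):
        rep_num = np.zeros((n_states,) + cube.values.shape[2:])
        np.add.at(rep_num, codes, (PW * cube.values).sum(axis=1))
        f0 = np.where(rep_num > 0, B * den[..., None] / np.maximum(rep_num, 1e-300), 1.0)
    for s_i, state in enumerate(geography.states):
        dev = np.abs(f0[s_i] - 1.0).max(axis=(0, 1, 3))
        logger.info(
            "raking %s: max |factor-1| by year = %s",
            state, np.array2string(dev, precision=3),
        )

    out = xr.DataArray(V, dims=cube.dims, coords=cube.coords)
    return set_lineage(out, **{**cube.attrs, "raked": True})
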