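"""Abridged life tables and Sullivan's method for healthy life expectancy.

A life table is built per stratum from age-specific mortality rates m_x via
the standard abridged recursion

    q_x = n * m_x / (1 + (n - a_x) * m_x),        terminal q = 1
    l_{x+n} = l_x (1 - q_x),                      radix l_0 = 100 000
    nL_x = n * l_{x+n} + a_x * (l_x - l_{x+n}),   terminal nL = l / m
    T_x = sum_{y >= x} nL_y,    e_x = T_x / l_x

Sullivan's method discounts the person-years lived in each age group by the
all-cause YLD rate d_y (proportional health loss per person-year):

    HALE_x = sum_{y >= x} nL_y (1 - d_y) / l_x

Years lived in poor health are e_x - HALE_x, and the proportion of life in
poor health is (e_x - HALE_x) / e_x.

All functions are vectorized: the age axis may be preceded by arbitrary
stratum dimensions and followed by a draw dimension.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .strata import AgeGrid

RADIX = 100_000.0


def lifetable_from_mx(
    mx: xr.DataArray,
    age_grid: AgeGrid,
    a: np.ndarray | None = None,
    a0_infant: float = 0.2,
) -> xr.Dataset:
    """Build abridged life tables from mortality rates.

    Parameters
    ----------
    mx
        Death rates per person-year with an ``age`` dimension of length
        ``age_grid.n_groups``; any leading stratum dimensions are allowed.
    age_grid
        The abridged age groups.
    a
        Average years lived within each group by those dying in it, one
        entry per group (the terminal entry is ignored).  Defaults to the
        demographic convention a_0 = ``a0_infant``, n/2 elsewhere.
    """
    if "age" not in mx.dims:
        raise ValueError("mx needs an 'age' dimension")
    if mx.sizes["age"] != age_grid.n_groups:
        raise ValueError("mx age dimension does not match the age grid")
    mx = mx.transpose(..., "age")
    m = np.asarray(mx.values, dtype=float)
    labels = age_grid.labels
    if np.any(m[..., -1] <= 0):
        raise ValueError(
            f"terminal age group {labels[-1]!r} has non-positive m_x; "
            "remaining life expectancy is undefined"
        )
    if np.any(m < 0):
        raise ValueError("negative m_x")

    n = age_grid.widths
    if a is None:
        a = age_grid.default_a(a0_infant)
    a = np.asarray(a, dtype=float)
    closed = slice(0, age_grid.n_groups - 1)
    if np.any(a[closed] < 0) or np.any(a[closed] > n[closed]):
        raise ValueError("a_x must lie in [0, n] for closed groups")

    q = np.empty_like(m)
    q[..., closed] = (n[closed] * m[..., closed]) / (
        1.0 + (n[closed] - a[closed]) * m[..., closed]
    )
    q[..., -1] = 1.0
    bad = (q < 0) | (q > 1)
    if bad.any():
        by_age = bad.reshape(-1, bad.shape[-1]).any(axis=0)
        idx = int(np.flatnonzero(by_age)[0])
        raise ValueError(f"q_x outside [0, 1] in age group {labels[idx]!r}")

    surv = np.cumprod(1.0 - q[..., :-1], axis=-1)
    l = np.concatenate(
        [np.full(m.shape[:-1] + (1,), RADIX), RADIX * surv], axis=-1
    )
    l_next = np.concatenate(
        [l[..., 1:], np.zeros(m.shape[:-1] + (1,))], axis=-1
    )
    d = l - l_next
    nL = np.empty_like(m)
    nL[..., closed] = n[closed] * l_next[..., closed] + a[closed] * d[..., closed]
    nL[..., -1] = l[..., -1] / m[..., -1]
    T = np.flip(np.cumsum(np.flip(nL, axis=-1), axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    dims = mx.dims
    coords = {k: v for k, v in mx.coords.items()}
    a_full = np.broadcast_to(a, m.shape)
    return xr.Dataset(
        {
            name: xr.DataArray(arr, dims=dims, coords=coords)
            for name, arr in (
                ("m", m), ("a", a_full), ("q", q), ("l", l),
                ("nL", nL), ("T", T), ("e", e),
            )
        }
    )


def hale_sullivan(lifetable: xr.Dataset, yld_rates: xr.DataArray) -> xr.DataArray:
    """HALE_x per age group: person-years discounted by the YLD rate.

    ``yld_rates`` must carry the same ``age`` coordinate as the life table;
    it may additionally carry a trailing ``draw`` dimension, in which case
    HALE is computed per draw.
    """
    if "age" not in yld_rates.dims:
        raise ValueError("yld_rates needs an 'age' dimension")
    if yld_rates.sizes["age"] != lifetable.sizes["age"]:
        raise ValueError(
            "yld_rates age length does not match the life table"
        )
    d = yld_rates
    if float(d.min()) < 0 or float(d.max()) > 1:
        raise ValueError("YLD rates must lie in [0, 1]")
    nL, l = lifetable["nL"], lifetable["l"]
    healthy = nL * (1.0 - d)  # broadcasts draw dimension if present
    healthy = healthy.transpose(..., "age") if "draw" not in healthy.dims else (
        healthy.transpose(..., "age", "draw")
    )
    axis = healthy.dims.index("age")
    rev = np.flip(np.cumsum(np.flip(healthy.values, axis=axis), axis=axis), axis=axis)
    Hsum = xr.DataArray(rev, dims=healthy.dims, coords=healthy.coords)
    with np.errstate(divide="ignore", invalid="ignore"):
        hale = Hsum / l
    return hale.where(l > 0, 0.0)


def poor_health_summaries(
    e: xr.DataArray | np.ndarray | float,
    hale: xr.DataArray | np.ndarray | float,
):
    """Years lived in poor health and the proportion of life in poor health.

    ``years_poor = e - HALE`` and ``prop_poor = years_poor / e`` (as a
    fraction; multiply by 100 to report percentages).
    """
    e_arr = np.asarray(getattr(e, "values", e), dtype=float)
    h_arr = np.asarray(getattr(hale, "values", hale), dtype=float)
    if np.any(e_arr == 0):
        raise ValueError("proportion of life in poor health undefined at e = 0")
    if np.any(h_arr > e_arr * (1 + 1e-12) + 1e-12):
        raise ValueError("HALE exceeds life expectancy")
    years_poor = e - hale
    prop_poor = years_poor / e
    return years_poor, prop_poor
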