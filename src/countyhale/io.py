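"""Readers and writers for the pipeline's on-disk interfaces.

Tabular inputs and summaries are delimited text (CSV) with fixed,
documented columns; every file written here round-trips through the
corresponding reader.  Draw cubes are stored as ``.npz`` archives (value
array plus named coordinate arrays and lineage metadata) because
million-row long-format CSVs would dominate run time; cube files are
run-time artifacts, not package fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xarray as xr

from .observations import IndicatorObservations
from .strata import AgeGrid, StrataCoords
from .synthetic_data import Geography

# ---------------------------------------------------------------------------
# geography

def write_geography(geography: Geography, path: Path) -> None:
    """geography.csv: county, state, neighbors (semicolon-joined ids)."""
    rows = []
    for i, county in enumerate(geography.county_ids):
        nbrs = geography.neighbors(county)
        rows.append(
            {
                "county": county,
                "state": geography.state_of[i],
                "component": geography.components[i],
                "neighbors": ";".join(nbrs),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_geography(path: Path) -> Geography:
    df = pd.read_csv(path, keep_default_na=False)
    ids = tuple(df["county"])
    lookup = {c: i for i, c in enumerate(ids)}
    rows, cols = [], []
    for i, nbrs in enumerate(df["neighbors"]):
        for nb in str(nbrs).split(";"):
            if nb:
                rows.append(i)
                cols.append(lookup[nb])
    A = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
    ).tocsr()
    return Geography(
        county_ids=ids,
        adjacency=A,
        state_of=tuple(df["state"]),
        components=tuple(int(c) for c in df["component"]),
    )


# ---------------------------------------------------------------------------
# stratum surfaces (no draw dimension) as long CSV

def surface_to_frame(da: xr.DataArray, value_name: str = "value") -> pd.DataFrame:
    return da.rename(value_name).to_series().reset_index()


def write_surface(da: xr.DataArray, path: Path, value_name: str = "value") -> None:
    surface_to_frame(da, value_name).to_csv(path, index=False)


def read_surface(
    path: Path, strata: StrataCoords, value_name: str = "value"
) -> xr.DataArray:
    df = pd.read_csv(path, keep_default_na=False)
    dims = strata.dims
    da = strata.empty()
    idx = [
        pd.Categorical(
            df[d].astype(str), categories=[str(c) for c in strata.coords()[d]]
        ).codes
        for d in dims
    ]
    da.values[tuple(idx)] = df[value_name].to_numpy(dtype=float)
    return da


def write_population(populations: xr.DataArray, path: Path) -> None:
    write_surface(populations, path, "population")


def read_population(path: Path, strata: StrataCoords) -> xr.DataArray:
    return read_surface(path, strata, "population")


def write_covariates(covariates: xr.DataArray, path: Path) -> None:
    surface_to_frame(covariates, "value").to_csv(path, index=False)


def read_covariates(path: Path) -> xr.DataArray:
    df = pd.read_csv(path, keep_default_na=False)
    names = list(dict.fromkeys(df["covariate"]))
    counties = list(dict.fromkeys(df["county"]))
    arr = (
        df.set_index(["covariate", "county"])["value"]
        .unstack()
        .loc[names, counties]
        .to_numpy(dtype=float)
    )
    return xr.DataArray(
        arr,
        dims=("covariate", "county"),
        coords={"covariate": names, "county": counties},
    )


# ---------------------------------------------------------------------------
# indicator observations

def write_indicator_obs(
    obs: dict[str, IndicatorObservations], path: Path
) -> None:
    """indicator_obs.csv: obs_id, indicator, level, n, k, strata, weights.

    ``strata`` is a semicolon-joined list of stratum ids
    (county|race|sex|age|year[|education]); ``weights`` aligns with it.
    """
    frames = []
    for ind, o in obs.items():
        ids = o.strata.stratum_ids()
        M = o.membership
        strata_col, weight_col = [], []
        for r in range(o.n_obs):
            sl = slice(M.indptr[r], M.indptr[r + 1])
            strata_col.append(";".join(ids[M.indices[sl]]))
            weight_col.append(
                ";".join(f"{w:.12g}" for w in M.data[sl])
            )
        frames.append(
            pd.DataFrame(
                {
                    "obs_id": o.meta.get("obs_id", pd.RangeIndex(o.n_obs)),
                    "indicator": ind,
                    "level": o.meta.get("level", "county"),
                    "n": o.n,
                    "k": o.k,
                    "strata": strata_col,
                    "weights": weight_col,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_indicator_obs(
    path: Path, strata: StrataCoords
) -> dict[str, IndicatorObservations]:
    df = pd.read_csv(path, keep_default_na=False)
    id_lookup = {s: i for i, s in enumerate(strata.stratum_ids())}
    out = {}
    for ind, grp in df.groupby("indicator", sort=False):
        rows, cols, data = [], [], []
        for r, (s_list, w_list) in enumerate(
            zip(grp["strata"], grp["weights"])
        ):
            for sid, w in zip(s_list.split(";"), w_list.split(";")):
                rows.append(r)
                cols.append(id_lookup[sid])
                data.append(float(w))
        M = sp.coo_matrix(
            (data, (rows, cols)), shape=(len(grp), strata.n_strata)
        ).tocsr()
        out[str(ind)] = IndicatorObservations(
            indicator=str(ind),
            strata=strata,
            n=grp["n"].to_numpy(),
            k=grp["k"].to_numpy(),
            membership=M,
            meta=grp[["obs_id", "level"]].reset_index(drop=True),
        )
    return out


# ---------------------------------------------------------------------------
# life tables

def write_lifetables(lt: xr.Dataset, path: Path) -> None:
    lt.to_dataframe().reset_index().to_csv(path, index=False)


def read_lifetables(path: Path, strata: StrataCoords) -> xr.Dataset:
    df = pd.read_csv(path, keep_default_na=False)
    dims = [d for d in ("county", "race", "sex", "age", "year") if d in df]
    coords = strata.coords()
    shape = tuple(len(coords[d]) for d in dims)
    idx = tuple(
        pd.Categorical(
            df[d].astype(str), categories=[str(c) for c in coords[d]]
        ).codes
        for d in dims
    )
    data_vars = {}
    for col in ("m", "a", "q", "l", "nL", "T", "e"):
        arr = np.full(shape, np.nan)
        arr[idx] = pd.to_numeric(df[col], errors="coerce").to_numpy()
        data_vars[col] = xr.DataArray(
            arr, dims=dims, coords={d: coords[d] for d in dims}
        )
    return xr.Dataset(data_vars)


# ---------------------------------------------------------------------------
# draw cubes

def save_cube(cube: xr.DataArray, path: Path) -> None:
    """Store a draw cube as a directory of ``.npy`` files plus JSON metadata.

    ``.npy`` bytes are deterministic (no embedded timestamps), so reruns
    with identical inputs produce byte-identical artifacts.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "values.npy", cube.values)
    meta: dict = {"dims": list(cube.dims), "attrs": {}}
    for d in cube.dims:
        np.save(path / f"coord_{d}.npy", np.asarray(cube[d].values))
    for key, val in cube.attrs.items():
        if isinstance(val, np.ndarray):
            np.save(path / f"attr_{key}.npy", val)
            meta.setdefault("array_attrs", []).append(key)
        else:
            meta["attrs"][key] = val
    (path / "meta.json").write_text(json.dumps(meta, sort_keys=True))


def load_cube(path: Path) -> xr.DataArray:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    dims = tuple(meta["dims"])
    coords = {d: np.load(path / f"coord_{d}.npy", allow_pickle=True) for d in dims}
    da = xr.DataArray(np.load(path / "values.npy"), dims=dims, coords=coords)
    da.attrs.update(meta["attrs"])
    for key in meta.get("array_attrs", []):
        da.attrs[key] = np.load(path / f"attr_{key}.npy")
    return da


def save_benchmarks(benchmarks: dict[str, xr.DataArray], path: Path) -> None:
    stacked = xr.concat(
        list(benchmarks.values()),
        dim=pd.Index(list(benchmarks.keys()), name="cause"),
    )
    save_cube(stacked, path)


def load_benchmarks(path: Path) -> dict[str, xr.DataArray]:
    stacked = load_cube(path)
    return {
        str(c): stacked.sel(cause=c).drop_vars("cause")
        for c in stacked["cause"].values
    }
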