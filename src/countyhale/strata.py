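"""Stratum definitions: age grids, demographic coordinate grids, draw cubes.

Every rate or estimate in the pipeline is keyed by a stratum — one
(county, race, sex, age group, year) cell, optionally extended by an
education category for the indicator models.  Surfaces are stored as dense
:class:`xarray.DataArray` objects over the full cartesian grid of those
coordinates, with an extra trailing ``draw`` dimension for draw cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import xarray as xr

#: canonical dimension order for stratum surfaces
STRATUM_DIMS = ("county", "race", "sex", "age", "year")
DRAW_DIM = "draw"

#: default abridged age grid: [0,1), [1,5), 5-year groups to [85, inf)
DEFAULT_AGE_STARTS: tuple[float, ...] = (0.0, 1.0) + tuple(
    float(a) for a in range(5, 90, 5)
)

RACE_LABELS = ("aian", "asian", "black", "latino", "white")
SEX_LABELS = ("female", "male")


@dataclass(frozen=True)
class AgeGrid:
    """Abridged age groups: half-open intervals covering [0, inf).

    The terminal group is open-ended.  ``a`` values (average person-years
    lived within the group by those dying in it) default to 0.2 for the
    infant group [0,1) and n/2 elsewhere, the standard demographic
    convention for abridged tables.
    """

    starts: tuple[float, ...] = DEFAULT_AGE_STARTS

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=float)
        if s.size < 1 or s[0] != 0.0:
            raise ValueError("age grid must start at 0")
        if np.any(np.diff(s) <= 0):
            raise ValueError("age group starts must be strictly increasing")

    @property
    def n_groups(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        """Group widths n; the terminal group has width inf."""
        s = np.asarray(self.starts, dtype=float)
        return np.append(np.diff(s), np.inf)

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        s = list(self.starts)
        for i, a in enumerate(s):
            if i == len(s) - 1:
                out.append(f"{a:g}+")
            else:
                out.append(f"{a:g}-{s[i + 1]:g}")
        return tuple(out)

    @property
    def midpoints(self) -> np.ndarray:
        """Group midpoints; the terminal group uses start + 7.5 years."""
        s = np.asarray(self.starts, dtype=float)
        mids = (s[:-1] + s[1:]) / 2.0
        return np.append(mids, s[-1] + 7.5)

    def default_a(self, a0_infant: float = 0.2) -> np.ndarray:
        """Default a_x: a0 for [0,1), n/2 for other closed groups.

        The terminal entry is NaN: person-years there are l/m, no a needed.
        """
        w = self.widths
        a = w / 2.0
        if w[0] == 1.0:
            a[0] = a0_infant
        a[-1] = np.nan
        return a


@dataclass(frozen=True)
class StrataCoords:
    """The cartesian coordinate grid that surfaces are defined over."""

    counties: tuple[str, ...]
    races: tuple[str, ...]
    sexes: tuple[str, ...] = SEX_LABELS
    age_grid: AgeGrid = field(default_factory=AgeGrid)
    years: tuple[int, ...] = tuple(range(2009, 2020))
    educations: tuple[str, ...] = ()  # empty = no education axis

    @property
    def dims(self) -> tuple[str, ...]:
        d = STRATUM_DIMS
        return d + ("education",) if self.educations else d

    @property
    def shape(self) -> tuple[int, ...]:
        base = (
            len(self.counties),
            len(self.races),
            len(self.sexes),
            self.age_grid.n_groups,
            len(self.years),
        )
        return base + (len(self.educations),) if self.educations else base

    @property
    def n_strata(self) -> int:
        return int(np.prod(self.shape))

    def coords(self) -> dict[str, Sequence]:
        c = {
            "county": list(self.counties),
            "race": list(self.races),
            "sex": list(self.sexes),
            "age": list(self.age_grid.labels),
            "year": list(self.years),
        }
        if self.educations:
            c["education"] = list(self.educations)
        return c

    def empty(self, fill: float = 0.0) -> xr.DataArray:
        return xr.DataArray(
            np.full(self.shape, fill, dtype=float),
            dims=self.dims,
            coords=self.coords(),
        )

    def from_flat(self, values: np.ndarray) -> xr.DataArray:
        """Reshape a flat vector in C order over ``dims`` into a surface."""
        return xr.DataArray(
            np.asarray(values, dtype=float).reshape(self.shape),
            dims=self.dims,
            coords=self.coords(),
        )

    def index_arrays(self) -> dict[str, np.ndarray]:
        """Per-dimension integer codes for every flat stratum, C order."""
        grids = np.meshgrid(
            *[np.arange(n) for n in self.shape], indexing="ij"
        )
        return {d: g.ravel() for d, g in zip(self.dims, grids)}

    def stratum_ids(self) -> np.ndarray:
        """Stable string key per flat stratum: county|race|sex|age|year[|edu]."""
        coords = self.coords()
        idx = self.index_arrays()
        cols = [
            np.asarray(coords[d], dtype=object)[idx[d]].astype(str)
            for d in self.dims
        ]
        out = cols[0]
        for c in cols[1:]:
            out = np.char.add(np.char.add(out, "|"), c)
        return out


# ---------------------------------------------------------------------------
# draw-cube helpers

def n_draws(cube: xr.DataArray) -> int:
    if DRAW_DIM not in cube.dims:
        raise ValueError("array has no draw dimension")
    return cube.sizes[DRAW_DIM]


def set_lineage(cube: xr.DataArray, **meta) -> xr.DataArray:
    """Attach draw-lineage metadata (n_models, draws_per_model, source ...)."""
    cube.attrs.update(meta)
    return cube


def require_aligned(a: xr.DataArray, b: xr.DataArray) -> None:
    """Draw cubes are combined only when strata and draw index align."""
    if a.dims != b.dims:
        raise ValueError(f"dimension mismatch: {a.dims} vs {b.dims}")
    for d in a.dims:
        if a.sizes[d] != b.sizes[d]:
            raise ValueError(
                f"size mismatch on {d!r}: {a.sizes[d]} vs {b.sizes[d]}"
            )
        if not np.array_equal(np.asarray(a[d]), np.asarray(b[d])):
            raise ValueError(f"coordinate mismatch on {d!r}")
    la, lb = a.attrs.get("model_of_draw"), b.attrs.get("model_of_draw")
    if la is not None and lb is not None and not np.array_equal(la, lb):
        raise ValueError("draw lineage mismatch between cubes")
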