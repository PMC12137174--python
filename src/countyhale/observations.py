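"""Survey-style binomial observations attached to sets of fine strata.

Real prevalence data arrive at mixed resolution: some observations refer to
a single fine (county, race, sex, age, year[, education]) stratum, others
only to a coarser merge of strata (for example all counties of a state).
The aggregation-consistent likelihood treats the success probability of an
observation as the population-weighted average of the prevalences of its
constituent fine strata, so each observation carries a weighted stratum set
rather than a single stratum index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .strata import StrataCoords


@dataclass
class IndicatorObservations:
    """Binomial observations for one indicator.

    ``membership`` is an (n_obs, n_strata) sparse matrix holding the
    population weight of each fine stratum within each observation's
    stratum set (zero means not a member); rows are normalized on demand.
    """

    indicator: str
    strata: StrataCoords
    n: np.ndarray
    k: np.ndarray
    membership: sp.csr_matrix
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        if self.n.shape != self.k.shape:
            raise ValueError("n and k must have equal length")
        if np.any(self.n <= 0):
            raise ValueError("observations must have n > 0")
        if np.any((self.k < 0) | (self.k > self.n)):
            raise ValueError("need 0 <= k <= n")
        self.membership = sp.csr_matrix(self.membership)
        if self.membership.shape != (self.n.size, self.strata.n_strata):
            raise ValueError("membership shape does not match n/strata")
        counts = np.diff(self.membership.indptr)
        if np.any(counts == 0):
            raise ValueError("every observation needs a non-empty stratum set")
        if np.any(self.membership.data <= 0) or not np.all(
            np.isfinite(self.membership.data)
        ):
            raise ValueError("stratum weights must be positive and finite")

    @property
    def n_obs(self) -> int:
        return int(self.n.size)

    def row_normalized(self) -> sp.csr_matrix:
        """Membership with rows scaled to sum to one (averaging weights)."""
        M = self.membership.tocsr(copy=True)
        rowsum = np.asarray(M.sum(axis=1)).ravel()
        inv = sp.diags(1.0 / rowsum)
        return (inv @ M).tocsr()
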