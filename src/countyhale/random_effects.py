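"""Structured random-effect precisions and exact samplers.

Three intrinsic Gaussian Markov random fields are used throughout:

* ICAR over the county adjacency graph — precision is the graph Laplacian
  ``D - A`` (degree minus adjacency), improper with one null vector (the
  constant) per connected component; realizations are constrained to sum
  to zero within each component.
* RW1 over an ordered index (year or age) — first-order random walk whose
  precision is the second-difference penalty matrix, improper with the
  constant null vector; realizations sum to zero.
* Centered exchangeable effects (race, education) — iid deviations with
  the mean removed, precision ``I - J/m``; like the intrinsic models its
  rows sum to zero, so the overall level lives in the intercept.

Sampling from these improper priors is done exactly on the constrained
subspace via the eigendecomposition pseudo-inverse: eigenvectors with
(numerically) zero eigenvalue span the null space and receive no variance.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

_NULL_TOL = 1e-9


def icar_precision(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """Graph Laplacian D - A of a symmetric, irreflexive adjacency."""
    A = sp.csr_matrix(adjacency)
    if (A != A.T).nnz:
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must have an empty diagonal")
    deg = np.asarray(A.sum(axis=1)).ravel()
    return (sp.diags(deg) - A).tocsr()


def rw1_precision(n: int) -> sp.csr_matrix:
    """First-order random-walk penalty: tridiagonal second-difference matrix."""
    if n < 1:
        raise ValueError("need at least one level")
    if n == 1:
        return sp.csr_matrix((1, 1))
    main = np.full(n, 2.0)
    main[0] = main[-1] = 1.0
    off = np.full(n - 1, -1.0)
    return sp.diags([off, main, off], [-1, 0, 1]).tocsr()


def centered_iid_precision(n: int) -> sp.csr_matrix:
    """Exchangeable deviations with the mean removed: I - J/n."""
    if n < 1:
        raise ValueError("need at least one level")
    return sp.csr_matrix(np.eye(n) - np.ones((n, n)) / n)


def structure_rank(Q: sp.spmatrix, n_components: int = 1) -> int:
    """Rank of an intrinsic precision: size minus number of null vectors."""
    return Q.shape[0] - n_components


def n_graph_components(adjacency: sp.spmatrix) -> int:
    ncomp, _ = connected_components(sp.csr_matrix(adjacency), directed=False)
    return ncomp


def sample_intrinsic(
    Q: sp.spmatrix,
    variance: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw from N(0, variance * Q^+) on the non-null eigenspace of Q.

    Returns an array of shape (size, n); each row sums to zero within every
    connected component because null-space directions carry no variance.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    n = Q.shape[0]
    if variance == 0:
        return np.zeros((size, n))
    evals, evecs = np.linalg.eigh(np.asarray(Q.todense()))
    keep = evals > _NULL_TOL * max(evals.max(), 1.0)
    scales = np.sqrt(variance / evals[keep])
    z = rng.standard_normal((size, int(keep.sum())))
    return (z * scales) @ evecs[:, keep].T
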