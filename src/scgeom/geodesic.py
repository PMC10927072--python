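"""Diffusion-pseudotime (DPT) geodesic distances.

The five scores measure geometry through a geodesic rather than Euclidean
lens: a kNN graph with an adaptive Gaussian kernel is turned into a diffusion
transition operator, and the DPT distance between two points accumulates
their separation across the operator's non-stationary eigenspaces,

    dpt(i, j)^2 = sum_s (lambda_s / (1 - lambda_s))^2 (psi_s(i) - psi_s(j))^2,

over the m leading eigenpairs with lambda_s < 1. Point pairs in different
connected components of the kNN graph have no finite geodesic; they are
marked infinite and later replaced by ``finite_fill`` with a fixed multiple
of the largest finite distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import ArpackError, eigsh
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateInputError, NumericalError
from .preprocess import PointCloud

__all__ = ["DiffusionConfig", "DistanceMatrix", "dpt_distance_matrix", "finite_fill"]

# eigenvalues at or numerically above this are stationary (or duplicated
# stationary in disconnected graphs) and excluded from the DPT sum
_STATIONARY_TOL = 1e-10

# dense eigendecomposition below this size; sparse Lanczos above
_DENSE_N = 400


@dataclass
class DiffusionConfig:
    """Parameters of the diffusion operator.

    n_graph_neighbors: neighborhood size of the kNN graph; also sets each
        point's adaptive kernel bandwidth (distance to its k-th neighbor).
    n_diffusion_components: number m of leading non-stationary eigenpairs
        kept in the DPT sum.
    infinity_fill_factor: multiple of the maximum finite distance used by
        ``finite_fill`` to replace infinite (cross-component) entries.
    """

    n_graph_neighbors: int = 15
    n_diffusion_components: int = 10
    infinity_fill_factor: float = 1.5

    def __post_init__(self):
        if self.n_graph_neighbors < 2:
            raise ValueError("n_graph_neighbors must be >= 2")
        if self.n_diffusion_components < 1:
            raise ValueError("n_diffusion_components must be >= 1")
        if self.infinity_fill_factor <= 0:
            raise ValueError("infinity_fill_factor must be positive")


@dataclass
class DistanceMatrix:
    """Symmetric n x n distance matrix with zero diagonal.

    Entries may be +inf between points with no finite geodesic; after
    ``finite_fill`` all entries are finite and nonnegative.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DegenerateInputError(f"distance matrix must be square, got {v.shape}")
        if not np.allclose(np.diag(v), 0.0):
            raise DegenerateInputError("distance matrix diagonal must be zero")
        finite = np.isfinite(v)
        if np.any(v[finite] < 0):
            raise DegenerateInputError("distance matrix has negative entries")
        if not np.array_equal(v, v.T):
            raise DegenerateInputError("distance matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


def _knn_affinity(X: np.ndarray, k: int):
    """Sparse symmetric adaptive-Gaussian affinity on the kNN graph.

    The k-th neighbor distance is found with ties broken by ascending point
    index (stable argsort, self excluded); the neighborhood then includes
    every point within that radius, so coincident points always receive
    identical affinity rows. Bandwidth sigma_i = distance to the k-th
    neighbor; edge weight exp(-d_ij^2 / (sigma_i^2 + sigma_j^2)).
    """
    n = X.shape[0]
    D = squareform(pdist(X))
    Dself = D.copy()
    np.fill_diagonal(Dself, -1.0)  # self sorts first even among coincident points
    order = np.argsort(Dself, axis=1, kind="stable")
    sigma = D[np.arange(n), order[:, k]]

    within = (D <= sigma[:, None]) & (Dself >= 0)  # tie-inclusive, self excluded
    rows, cols = np.nonzero(within)
    denom = sigma[rows] ** 2 + sigma[cols] ** 2
    d2 = D[rows, cols] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, np.exp(-d2 / np.where(denom > 0, denom, 1.0)), (d2 == 0) * 1.0)
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = (W + W.T) * 0.5
    return W


def dpt_distance_matrix(pc: PointCloud, cfg: DiffusionConfig = DiffusionConfig()) -> DistanceMatrix:
    """DPT geodesic distance matrix of a point cloud.

    Builds the kNN adaptive-Gaussian affinity, row-normalizes to a transition
    operator (diagonalized through its symmetric conjugate for a real
    spectrum), and evaluates the DPT distance over the
    ``n_diffusion_components`` leading non-stationary eigenpairs. Pairs in
    different connected components are set to +inf.
    """
    n = pc.n
    if n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {n}")
    k = cfg.n_graph_neighbors
    if n < k + 1:
        raise DegenerateInputError(f"need n >= n_graph_neighbors + 1 = {k + 1}, got {n}")

    W = _knn_affinity(pc.coords, k)
    n_comp, comp_labels = connected_components(W > 0, directed=False)

    deg = np.asarray(W.sum(axis=1)).ravel()
    deg = np.maximum(deg, np.finfo(float).tiny)
    inv_sqrt = 1.0 / np.sqrt(deg)
    # symmetric conjugate A = D^-1/2 W D^-1/2 of the transition operator D^-1 W
    A = sp.diags(inv_sqrt) @ W @ sp.diags(inv_sqrt)

    m = min(cfg.n_diffusion_components, n - n_comp)
    want = min(n - 1, m + n_comp + 5)
    try:
        if n <= _DENSE_N or want >= n - 1:
            lam, V = np.linalg.eigh(A.toarray())
        else:
            # deterministic Lanczos start vector: ARPACK's internal RNG is
            # stateful across calls and would break byte-identical reruns
            v0 = np.full(n, 1.0 / np.sqrt(n))
            lam, V = eigsh(A, k=want, which="LA", v0=v0)
    except (np.linalg.LinAlgError, ArpackError) as exc:
        raise NumericalError(
            f"eigendecomposition failed for n={n}, k={k}: {exc}"
        ) from exc

    keep = lam < 1.0 - _STATIONARY_TOL
    lam, V = lam[keep], V[:, keep]
    top = np.argsort(lam)[::-1][:m]
    lam, V = lam[top], V[:, top]

    psi = V * inv_sqrt[:, None]  # right eigenvectors of the transition operator
    M = psi * (lam / (1.0 - lam))[None, :]
    d = squareform(pdist(M))
    if n_comp > 1:
        cross = comp_labels[:, None] != comp_labels[None, :]
        d[cross] = np.inf
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d)


def finite_fill(dm: DistanceMatrix, infinity_fill_factor: float = 1.5) -> DistanceMatrix:
    """Replace non-finite entries by a fixed multiple of the max finite entry.

    Returns the input unchanged (same object) when already finite.
    """
    v = dm.values
    finite_mask = np.isfinite(v)
    off = ~np.eye(dm.n, dtype=bool)
    if not np.any(finite_mask & off):
        raise DegenerateInputError("all off-diagonal entries are non-finite")
    if finite_mask.all():
        return dm
    fill = infinity_fill_factor * v[finite_mask].max()
    out = np.where(finite_mask, v, fill)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(values=out)
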