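"""Cell-cell affinity graph with heat-kernel weights and its Laplacian.

The graph encodes local geometry of the cells: an edge joins cells that are
k-nearest neighbours of each other (in either direction), weighted by the
heat kernel exp(-||c_i - c_j||^2 / sigma). The Laplacian L = D - A turns
that geometry into the smoothness penalty Tr(B^T L B) used to regularize
the cluster-evidence matrix B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

__all__ = ["AffinityGraph", "build_affinity", "graph_penalty"]


@dataclass
class AffinityGraph:
    """kNN heat-kernel affinity over cells.

    Attributes
    ----------
    A
        Symmetric non-negative sparse weight matrix, zero diagonal,
        entries in [0, 1].
    n_neighbors
        Neighbourhood size used to build the graph.
    sigma
        Resolved heat-kernel bandwidth (after "auto" resolution).
    """

    A: sp.csr_matrix
    n_neighbors: int
    sigma: float
    _L: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return self.A.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Vector of degrees D_ii = sum_j A_ij."""
        return np.asarray(self.A.sum(axis=1)).ravel()

    @property
    def D(self) -> sp.csr_matrix:
        return sp.diags(self.degrees).tocsr()

    @property
    def L(self) -> sp.csr_matrix:
        """Graph Laplacian L = D - A (cached)."""
        if self._L is None:
            self._L = laplacian(self)
        return self._L

    def to_mtx(self, path) -> None:
        """Serialize the affinity matrix as Matrix Market for inspection."""
        from scipy.io import mmwrite

        mmwrite(str(path), sp.coo_matrix(self.A))


def build_affinity(points, n_neighbors: int = 15, sigma="auto") -> AffinityGraph:
    """Build the kNN heat-kernel affinity graph over rows of ``points``.

    A_ij = exp(-||c_i - c_j||^2 / sigma) whenever c_i is among the
    ``n_neighbors`` nearest neighbours of c_j or vice versa, and 0 otherwise.

    Parameters
    ----------
    points
        cell x feature real matrix (dense or sparse).
    n_neighbors
        Neighbourhood size; must satisfy ``1 <= n_neighbors < n_cells``.
    sigma
        Heat-kernel bandwidth. ``"auto"`` resolves to the mean squared
        Euclidean distance over the retained kNN edges, which makes the
        weights scale-invariant. If every retained distance is zero
        (all-identical points) sigma falls back to 1 with a logged warning.

    Notes
    -----
    Exact kNN by full pairwise distances (desk scale); ties in distance are
    broken toward the lower cell index so the graph is deterministic.
    """
    if sp.issparse(points):
        points = points.toarray()
    X = np.asarray(points, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("build_affinity needs at least 2 cells (rows)")
    n = X.shape[0]
    n_neighbors = int(n_neighbors)
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if n_neighbors >= n:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be smaller than the number of cells n={n}"
        )

    d2 = squareform(pdist(X, metric="sqeuclidean"))
    np.fill_diagonal(d2, np.inf)
    # stable argsort on distances => ties broken by lower index
    order = np.argsort(d2, axis=1, kind="stable")[:, :n_neighbors]

    directed = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), n_neighbors)
    directed[rows, order.ravel()] = True
    mutual = directed | directed.T

    edge_d2 = d2[mutual]
    if sigma == "auto":
        mean_d2 = float(edge_d2.mean())
        if mean_d2 <= 0.0:
            logger.warning(
                "all retained kNN distances are zero (identical points); "
                "falling back to sigma=1"
            )
            sigma_val = 1.0
        else:
            sigma_val = mean_d2
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")

    W = np.zeros((n, n))
    W[mutual] = np.exp(-edge_d2 / sigma_val)
    A = sp.csr_matrix(W)
    return AffinityGraph(A=A, n_neighbors=n_neighbors, sigma=sigma_val)


def laplacian(graph: AffinityGraph) -> sp.csr_matrix:
    """Return L = D - A with D_ii = sum_j A_ij.

    Raises if A is not symmetric: asymmetry means the graph was constructed
    outside the documented contract.
    """
    A = graph.A
    asym = abs(A - A.T)
    if asym.nnz and asym.max() > 1e-12:
        raise ValueError("internal contract violated: affinity matrix is not symmetric")
    return (sp.diags(np.asarray(A.sum(axis=1)).ravel()) - A).tocsr()


def graph_penalty(B, graph: AffinityGraph) -> float:
    """Smoothness of the per-cell embedding rows of B over the graph.

    Computed as the trace form Tr(B^T L B), which equals the direct pairwise
    sum (1/2) * sum_ij A_ij ||b_i - b_j||^2. Zero exactly when B is constant
    on every connected component.
    """
    B = np.asarray(B, dtype=np.float64)
    if B.ndim == 1:
        B = B[:, None]
    if B.shape[0] != graph.n_cells:
        raise ValueError(
            f"B has {B.shape[0]} rows but the graph has {graph.n_cells} vertices"
        )
    val = float(np.sum(B * (graph.L @ B)))
    # the quadratic form is PSD; clip rounding-level negatives
    return max(val, 0.0)
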