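"""kNN Gaussian similarity over samples and its unnormalized Laplacian.

Samples that are close in expression space should receive similar soft
cluster assignments; the quadratic Tr(Z^T L Z) enforces this, since it
equals 1/2 * sum_ij ||z_i - z_j||^2 S_ij.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import ExpressionDataset, ValidationError


@dataclass(frozen=True)
class SimilarityGraph:
    S: np.ndarray  # n x n, symmetric, zero diagonal, entries in [0, 1]
    k: int
    t: float

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")
        if np.any(np.diag(S) != 0):
            raise ValidationError("similarity diagonal must be zero")
        if np.any(S < 0) or np.any(S > 1 + 1e-12):
            raise ValidationError("similarities must lie in [0, 1]")


@dataclass(frozen=True)
class GraphLaplacian:
    L: np.ndarray
    D: np.ndarray  # diagonal degree matrix

    def __post_init__(self):
        object.__setattr__(self, "L", np.asarray(self.L, dtype=float))
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))


def knn_similarity(data: ExpressionDataset, k: int = 5, t: float = 0.5) -> SimilarityGraph:
    """Heat-kernel similarity on mutual-or kNN sample pairs.

    S_ij = exp(-||x_i - x_j||^2 / (2 t^2)) if i is among j's k nearest
    neighbors or vice versa, else 0.  A sample is never its own neighbor;
    ties at the k-th distance break toward the smaller sample index.
    """
    n = data.n_samples
    if k >= n:
        raise ValidationError(f"k={k} must be < number of samples n={n}")
    if t <= 0:
        raise ValidationError("kernel width t must be positive")
    D2 = squareform(pdist(data.values.T, metric="sqeuclidean"))
    neighbor = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # stable sort on distance, then index, makes ties deterministic
        order = others[np.lexsort((others, D2[i, others]))]
        neighbor[i, order[:k]] = True
    mask = neighbor | neighbor.T
    S = np.where(mask, np.exp(-D2 / (2.0 * t * t)), 0.0)
    np.fill_diagonal(S, 0.0)
    return SimilarityGraph(S, k=k, t=t)


def graph_laplacian(graph: SimilarityGraph) -> GraphLaplacian:
    """Unnormalized Laplacian L = D - S; rows sum to zero."""
    S = graph.S
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValidationError("similarity matrix must be symmetric")
    D = np.diag(S.sum(axis=1))
    return GraphLaplacian(D - S, D)


def laplacian_quadratic(Z: np.ndarray, lap: GraphLaplacian) -> float:
    """Tr(Z^T L Z), nonnegative up to round-off."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != lap.L.shape[0]:
        raise ValidationError(
            f"Z has {Z.shape[0] if Z.ndim == 2 else '?'} rows, "
            f"L is {lap.L.shape[0]} x {lap.L.shape[0]}"
        )
    return float(np.trace(Z.T @ lap.L @ Z))
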