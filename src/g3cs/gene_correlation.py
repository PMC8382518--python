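"""Gene-pair covariance and the adjusted correlation penalty.

The redundancy penalty is the quadratic form Tr(P^T M_bar P), where M_bar
aggregates each gene's covariance with all other genes so that selecting
several mutually correlated genes costs more than selecting independent
ones.  Covariance is taken across samples with the unbiased n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset, ValidationError


@dataclass(frozen=True)
class GeneCovariance:
    """m x m gene covariance matrix M and the per-gene means."""

    M: np.ndarray
    gene_means: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "gene_means",
                           np.asarray(self.gene_means, dtype=float))
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValidationError("covariance matrix must be square")
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValidationError("covariance matrix must be symmetric")


@dataclass(frozen=True)
class AdjustedCorrelation:
    """Adjusted gene-correlation matrix M_bar and how it was formed.

    ``mode`` records which reading produced it: "printed" keeps the diagonal
    of M and overwrites each off-diagonal (i, j) with gene i's off-diagonal
    row sum; "diag-rowsum" puts that row sum on the diagonal and keeps the
    off-diagonal covariances.  ``symmetrized`` notes whether the result was
    replaced by its symmetric part (the penalty only senses that part, and
    symmetrizing makes the gradient 2 M_bar P exact).
    """

    M_bar: np.ndarray
    mode: str
    symmetrized: bool

    def __post_init__(self):
        M_bar = np.asarray(self.M_bar, dtype=float)
        object.__setattr__(self, "M_bar", M_bar)
        if not np.all(np.isfinite(M_bar)):
            raise ValidationError("adjusted correlation has non-finite entries")
        if self.symmetrized and not np.allclose(M_bar, M_bar.T, atol=1e-10):
            raise ValidationError("symmetrized matrix is not symmetric")

    @property
    def symmetric_part(self) -> np.ndarray:
        return 0.5 * (self.M_bar + self.M_bar.T)


def covariance_matrix(data: ExpressionDataset) -> GeneCovariance:
    """Gene-pair covariance across samples.

    M[i, j] = sum_s (X[i, s] - mean_i)(X[j, s] - mean_j) / (n - 1).
    A constant gene yields a zero row and column.
    """
    X = data.values
    if X.shape[1] < 2:
        raise ValidationError("covariance undefined for fewer than 2 samples")
    means = X.mean(axis=1)
    M = np.cov(X, ddof=1)
    M = 0.5 * (M + M.T)  # kill round-off asymmetry
    return GeneCovariance(M, means)


def adjust_correlation(
    cov: GeneCovariance,
    mode: str = "printed",
    symmetrize: bool = True,
) -> AdjustedCorrelation:
    """Aggregate per-gene covariances into the redundancy matrix M_bar."""
    if mode not in ("printed", "diag-rowsum"):
        raise ValidationError(f"unknown adjustment mode {mode!r}")
    M = cov.M
    offdiag_rowsum = M.sum(axis=1) - np.diag(M)
    if mode == "printed":
        M_bar = np.tile(offdiag_rowsum[:, None], (1, M.shape[0]))
        np.fill_diagonal(M_bar, np.diag(M))
    else:
        M_bar = M.copy()
        np.fill_diagonal(M_bar, offdiag_rowsum)
    if symmetrize:
        M_bar = 0.5 * (M_bar + M_bar.T)
    return AdjustedCorrelation(M_bar, mode=mode, symmetrized=symmetrize)


def correlation_penalty(P: np.ndarray, adj: AdjustedCorrelation) -> float:
    """Tr(P^T M_bar P); invariant to replacing M_bar by its symmetric part."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != adj.M_bar.shape[0]:
        raise ValidationError(
            f"P has {P.shape[0] if P.ndim == 2 else '?'} rows, "
            f"M_bar is {adj.M_bar.shape[0]} x {adj.M_bar.shape[0]}"
        )
    return float(np.trace(P.T @ adj.M_bar @ P))
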