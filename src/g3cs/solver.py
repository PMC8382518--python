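"""Alternating solver for the correlation-guided selection objective.

The objective over (P, F, Z) is

    ||P^T X - F Z^T||_F^2 + alpha ||P||_{2,1}
        + beta Tr(P^T M_bar P) + gamma Tr(Z^T L Z)
    s.t. F^T F = I,  Z^T Z ~ I,  Z >= 0,

minimized by block updates: P has a closed form through the standard
reweighted-l2,1 trick (diagonal matrix G of inverse row norms); F solves an
orthogonal Procrustes problem (exactly, via the polar factor, or by the
literal penalty-gradient rule); Z takes a nonnegativity-preserving
multiplicative step derived from the KKT conditions of the kappa-penalized
subproblem.  Orthonormality of Z is enforced softly, so the objective trace
is monotone only empirically, not by theorem.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .data_io import ExpressionDataset, RunConfig, ValidationError
from .gene_correlation import (
    AdjustedCorrelation,
    adjust_correlation,
    covariance_matrix,
    correlation_penalty,
)
from .sample_graph import GraphLaplacian, graph_laplacian, knn_similarity, laplacian_quadratic

logger = logging.getLogger(__name__)

_DELTA = 1e-12  # multiplicative-update denominator floor
_INNER_MAX = 15   # cap on inner P/G reweighting iterations per sweep
_INNER_TOL = 1e-7  # relative P-change declaring the inner loop stationary


@dataclass
class ObjectiveParts:
    residual: float
    sparsity: float
    correlation: float
    manifold: float

    @property
    def total(self) -> float:
        return self.residual + self.sparsity + self.correlation + self.manifold


@dataclass
class SolverState:
    """The solver variables plus bookkeeping for one fit."""

    P: np.ndarray  # m x c projection; row norms score genes
    F: np.ndarray  # c x c, F^T F = I
    Z: np.ndarray  # n x c, nonnegative soft cluster indicators
    G: np.ndarray  # diagonal of the l2,1 reweighting matrix (length m)
    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def objective(
    X: np.ndarray,
    state: SolverState,
    adj: AdjustedCorrelation,
    lap: GraphLaplacian,
    config: RunConfig,
) -> ObjectiveParts:
    """Evaluate each objective term at the current (P, F, Z)."""
    P, F, Z = state.P, state.F, state.Z
    if P.shape[0] != X.shape[0] or Z.shape[0] != X.shape[1]:
        raise ValidationError("objective: P/Z shapes inconsistent with X")
    residual = float(np.linalg.norm(P.T @ X - F @ Z.T, "fro") ** 2)
    sparsity = config.alpha * float(np.linalg.norm(P, axis=1).sum())
    correlation = config.beta * correlation_penalty(P, adj)
    manifold = config.gamma * laplacian_quadratic(Z, lap)
    return ObjectiveParts(residual, sparsity, correlation, manifold)


def compute_G(P: np.ndarray, epsilon: float) -> np.ndarray:
    """Diagonal reweighting matrix G_ii = 1 / (2 max(||P^i||_2, epsilon))."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    row_norms = np.linalg.norm(np.asarray(P, dtype=float), axis=1)
    return np.diag(1.0 / (2.0 * np.maximum(row_norms, epsilon)))


def update_P(
    X: np.ndarray,
    Z: np.ndarray,
    F: np.ndarray,
    G: np.ndarray,
    adj: AdjustedCorrelation,
    alpha: float,
    beta: float,
    _system_base: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form P solving (X X^T + alpha G + beta M_bar) P = X Z F^T.

    The symmetric part of M_bar is used so the system matrix matches the
    exact gradient of the quadratic penalty.  A singular system (possible
    only at alpha = beta = 0) is ridge-stabilized with a warning.
    ``_system_base`` lets callers pass the precomputed constant part
    X X^T + beta M_bar_sym of the system matrix.
    """
    if _system_base is None:
        _system_base = X @ X.T + beta * adj.symmetric_part
    A = _system_base + alpha * G
    B = X @ Z @ F.T
    try:
        return scipy.linalg.solve(A, B, assume_a="sym", check_finite=False)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        ridge = 1e-10 * max(np.trace(A) / A.shape[0], 1.0)
        warnings.warn("singular P-system; applying ridge stabilization")
        return scipy.linalg.solve(A + ridge * np.eye(A.shape[0]), B,
                                  assume_a="sym", check_finite=False)


def update_F(
    P: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    F_current: np.ndarray,
    rho: float = 1e3,
    method: str = "procrustes",
) -> np.ndarray:
    """Orthogonality-constrained F update with target W = P^T X Z.

    method="procrustes" returns the exact minimizer of ||W - F||_F subject
    to F^T F = I, i.e. the polar factor U V^T of W.  method="multiplicative"
    applies the literal penalty-gradient assignment
    F_ij = W_ij / [F + rho (F F^T F - F)]_ij once, with a sign-preserving
    denominator floor; it is retained for fidelity experiments only.
    """
    W = P.T @ X @ Z
    if method == "procrustes":
        U, s, Vt = scipy.linalg.svd(W)
        if s.size and s[-1] < _DELTA:
            warnings.warn("rank-deficient Procrustes target; perturbing")
            U, s, Vt = scipy.linalg.svd(W + _DELTA * np.eye(W.shape[0]))
        return U @ Vt
    elif method == "multiplicative":
        F = np.asarray(F_current, dtype=float)
        den = F + rho * (F @ F.T @ F - F)
        sign = np.where(den >= 0, 1.0, -1.0)
        den = sign * np.maximum(np.abs(den), _DELTA)
        return W / den
    raise ValidationError(f"unknown F-update method {method!r}")


def update_Z(
    X: np.ndarray,
    P: np.ndarray,
    F: np.ndarray,
    Z_current: np.ndarray,
    lap: GraphLaplacian,
    gamma: float,
    kappa: float = 1e4,
    exponent: float = 0.5,
) -> np.ndarray:
    """One KKT-derived multiplicative step on the nonnegative indicator Z.

    The Laplacian gradient 2 gamma L Z is split as L = D - S so the
    subtracted part (S) lands in the numerator and the added part (D) in the
    denominator, keeping every factor nonnegative; the possibly-signed
    regression gradient term X^T P F is split into its positive and negative
    parts the same way.  The ratio is raised to ``exponent`` before being
    applied: 1.0 is the plain KKT ratio, whose column-norm map oscillates
    with period 2 when the kappa penalty dominates; the default 0.5 is the
    standard square-root damping from orthogonal NMF, which has the same
    fixed points and converges.
    """
    Z = np.asarray(Z_current, dtype=float)
    if np.any(Z < 0):
        raise ValidationError("Z must be elementwise nonnegative")
    S = lap.D - lap.L
    D_diag = np.diag(lap.D)
    XPF = X.T @ P @ F
    pos = np.maximum(XPF, 0.0)
    neg = np.maximum(-XPF, 0.0)
    num = 2.0 * pos + 2.0 * gamma * (S @ Z) + kappa * Z
    den = (
        2.0 * neg
        + 2.0 * Z @ (F.T @ F)
        + 2.0 * gamma * D_diag[:, None] * Z
        + kappa * Z @ (Z.T @ Z)
        + _DELTA
    )
    ratio = num / den
    if exponent != 1.0:
        ratio = ratio ** exponent
    return Z * ratio


def _initial_Z(S: np.ndarray, c: int, seed: int) -> np.ndarray:
    """Nonnegative near-orthonormal indicator from spectral clustering of S.

    Samples are clustered into c groups on the leading eigenvectors of S,
    the hard indicator is column-normalized (columns then have unit norm,
    so Z starts exactly column-orthonormal), and 1e-4 is added everywhere
    so multiplicative updates are not zero-locked.  The perturbation is
    kept small because it is the only source of initial orthonormality
    violation, which the kappa penalty then has to repair.
    """
    n = S.shape[0]
    n_eig = min(c, n - 1)
    vals, vecs = scipy.linalg.eigh(S)
    embedding = vecs[:, ::-1][:, :n_eig]
    km = KMeans(n_clusters=c, n_init=10, random_state=seed % (2**31))
    labels = km.fit_predict(embedding)
    Z = np.zeros((n, c))
    Z[np.arange(n), labels] = 1.0
    counts = np.maximum(Z.sum(axis=0), 1.0)
    Z /= np.sqrt(counts)
    return Z + 1e-4


def fit(data: ExpressionDataset, config: RunConfig, callback=None) -> SolverState:
    """Run the alternating solver to convergence on an expression dataset.

    Precomputes the adjusted correlation matrix and the sample-graph
    Laplacian once, then sweeps P (with G refreshed from the current P),
    F, and Z until the relative objective change falls below ``config.tol``
    or ``config.max_iter`` sweeps are reached.  Deterministic given
    ``config.seed``.  ``callback(state)``, if given, is invoked after every
    full sweep (useful for monitoring constraint satisfaction).
    """
    config.validate_against(data)
    data_fit = data.standardized() if config.standardize else data
    X = data_fit.values
    m, n = X.shape
    c = config.c

    adj = adjust_correlation(
        covariance_matrix(data_fit),
        mode=config.correlation_mode,
        symmetrize=config.symmetrize,
    )
    graph = knn_similarity(data_fit, k=config.k_neighbors, t=config.t_width)
    lap = graph_laplacian(graph)

    Z = _initial_Z(graph.S, c, config.seed)
    F = np.eye(c)
    system_base = X @ X.T + config.beta * adj.symmetric_part
    # First P solve uses unit row weights (G = I/2), i.e. a plain ridge on
    # the rows, because row norms are undefined before P exists.
    G = 0.5 * np.eye(m)
    P = update_P(X, Z, F, G, adj, config.alpha, config.beta,
                 _system_base=system_base)

    state = SolverState(P=P, F=F, Z=Z, G=G)
    parts = objective(X, state, adj, lap, config)
    state.objective_trace.append(parts.total)
    _check_finite(parts)

    prev = parts.total
    for sweep in range(1, config.max_iter + 1):
        # inner reweighted-l2,1 loop: alternate G and the closed-form P
        # until the P block is (near-)stationary for the current F, Z
        for _ in range(_INNER_MAX):
            state.G = compute_G(state.P, config.epsilon)
            P_new = update_P(X, state.Z, state.F, state.G, adj,
                             config.alpha, config.beta,
                             _system_base=system_base)
            delta = np.linalg.norm(P_new - state.P)
            state.P = P_new
            if delta <= _INNER_TOL * max(np.linalg.norm(state.P), 1e-12):
                break
        state.F = update_F(state.P, X, state.Z, state.F,
                           rho=config.rho, method=config.f_method)
        state.Z = update_Z(X, state.P, state.F, state.Z, lap,
                           config.gamma, kappa=config.kappa)
        parts = objective(X, state, adj, lap, config)
        _check_finite(parts)
        total = parts.total
        state.objective_trace.append(total)
        state.iterations = sweep
        logger.info(
            "sweep %d: residual=%.6g sparsity=%.6g correlation=%.6g "
            "manifold=%.6g total=%.6g",
            sweep, parts.residual, parts.sparsity, parts.correlation,
            parts.manifold, total,
        )
        if callback is not None:
            callback(state)
        if abs(total - prev) / max(abs(prev), 1e-12) < config.tol:
            state.converged = True
            break
        prev = total
    return state


def _check_finite(parts: ObjectiveParts) -> None:
    for name in ("residual", "sparsity", "correlation", "manifold"):
        if not np.isfinite(getattr(parts, name)):
            raise FloatingPointError(
                f"objective term {name!r} became non-finite; aborting"
            )
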