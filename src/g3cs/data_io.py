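"""Expression-matrix I/O, run configuration, and score tables.

Expression matrices are plain delimited text with one identifier row
(samples) and one identifier column (genes); the in-memory convention is
always genes x samples.  No normalization is applied on read; an optional
per-gene standardization helper is provided separately because silent
transforms would change the gene covariance the selection model penalizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a structural contract (shapes, identifiers, ranges)."""


class ParseError(ValueError):
    """A file cell could not be interpreted as a number."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x samples expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray, shape (m, n)
        Expression values, genes in rows, samples in columns. Must be finite.
    gene_ids : list of str
        m unique gene identifiers.
    sample_ids : list of str
        n unique sample identifiers.
    labels : list, optional
        Per-sample class identifiers, used only by the evaluation harness;
        the selection itself never sees them.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    labels: tuple | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        m, n = values.shape
        # m = 1 is allowed so a single-gene subset remains representable;
        # read_expression enforces >= 2 genes on ingestion
        if m < 1 or n < 2:
            raise ValidationError(
                f"need at least 1 gene and 2 samples, got {m} x {n}"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {bad[0]}, sample {bad[1]}"
            )
        if len(self.gene_ids) != m:
            raise ValidationError("gene_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match column count")
        if len(set(self.gene_ids)) != m:
            raise ValidationError("gene identifiers are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample identifiers are not unique")
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValidationError("labels length does not match sample count")
            if len(set(self.labels)) < 2:
                raise ValidationError("labels must contain at least 2 classes")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_labels(self, labels: Sequence) -> "ExpressionDataset":
        return replace(self, labels=tuple(labels))

    def standardized(self) -> "ExpressionDataset":
        """Per-gene standardization (mean 0, sd 1; constant genes left at 0)."""
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return replace(self, values=(self.values - mu) / sd)


@dataclass(frozen=True)
class RunConfig:
    """Hyperparameters and solver controls for one selection run.

    alpha, beta, gamma weight the row-sparsity, gene-correlation and
    manifold terms of the objective; c is the number of sample clusters
    (columns of P, F, Z); k_neighbors/t_width shape the sample graph;
    rho and kappa are the orthogonality penalty constants of the F and Z
    subproblems; epsilon floors row norms in the reweighting matrix G.
    """

    alpha: float = 10.0
    beta: float = 1e-3
    gamma: float = 1.0
    c: int = 2
    k_neighbors: int = 5
    t_width: float = 0.5
    rho: float = 1e3
    kappa: float = 1e4
    max_iter: int = 200
    tol: float = 1e-5
    epsilon: float = 1e-8
    seed: int = 0
    n_select: int = 10
    correlation_mode: str = "printed"
    symmetrize: bool = True
    f_method: str = "procrustes"
    standardize: bool = False

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValidationError("alpha, beta, gamma must be nonnegative")
        if self.c < 1:
            raise ValidationError("c must be a positive integer")
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be positive")
        for name in ("t_width", "rho", "kappa", "tol", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be positive")
        if self.n_select < 1:
            raise ValidationError("n_select must be positive")
        if self.correlation_mode not in ("printed", "diag-rowsum"):
            raise ValidationError("correlation_mode must be printed|diag-rowsum")
        if self.f_method not in ("procrustes", "multiplicative"):
            raise ValidationError("f_method must be procrustes|multiplicative")

    def validate_against(self, data: ExpressionDataset) -> None:
        if self.k_neighbors >= data.n_samples:
            raise ValidationError(
                f"k_neighbors={self.k_neighbors} must be < n={data.n_samples}"
            )
        if self.c > min(data.n_genes, data.n_samples):
            raise ValidationError(
                f"c={self.c} exceeds min(m, n)={min(data.n_genes, data.n_samples)}"
            )


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene importance scores with a deterministic descending rank."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray
    rank: np.ndarray = field(default=None)  # rank[r] = gene index at rank r

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if any(g == "" for g in self.gene_ids):
            raise ValidationError("empty-string gene_id")
        if scores.ndim != 1 or len(self.gene_ids) != scores.size:
            raise ValidationError("gene_ids and scores lengths differ")
        if np.any(scores < 0) or not np.all(np.isfinite(scores)):
            raise ValidationError("scores must be finite and nonnegative")
        if self.rank is None:
            order = np.lexsort((np.arange(scores.size), -scores))
            object.__setattr__(self, "rank", order)
        else:
            rank = np.asarray(self.rank, dtype=int)
            object.__setattr__(self, "rank", rank)
            if sorted(rank.tolist()) != list(range(scores.size)):
                raise ValidationError("rank is not a permutation of gene indices")
            if np.any(np.diff(scores[rank]) > 0):
                raise ValidationError("rank is not in descending score order")


def _read_table(path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValidationError(f"{path}: empty table")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{df.index[i]!r}, column {col!r}"
                ) from None
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    return out


def read_expression(
    path,
    orientation: str = "genes-in-rows",
    delimiter: str = "\t",
) -> ExpressionDataset:
    """Read a delimited expression matrix into an ExpressionDataset.

    Parameters
    ----------
    path : path-like
        Delimited text file; first row and first column hold identifiers.
    orientation : {"genes-in-rows", "genes-in-columns"}
        Layout of the file; the returned dataset is always genes x samples.
    delimiter : str
        Field separator, default tab.
    """
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_table(path, delimiter)
    if orientation == "genes-in-columns":
        df = df.T
    gene_ids = list(df.index)
    sample_ids = list(df.columns)
    if len(gene_ids) < 2 or len(sample_ids) < 2:
        raise ValidationError(
            f"{path}: need at least 2 genes and 2 samples, got "
            f"{len(gene_ids)} x {len(sample_ids)}"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{path}: duplicate gene identifiers")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample identifiers")
    return ExpressionDataset(df.to_numpy(), gene_ids, sample_ids)


def read_labels(path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (sample_id, label) file into a mapping."""
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: label file needs two columns")
    return dict(zip(df[0], df[1]))


def write_scores(table: GeneScoreTable, path) -> None:
    """Write a gene-score table as TSV (gene_id, score, rank), rank order."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\tscore\trank\n")
        for r, idx in enumerate(table.rank, start=1):
            fh.write(f"{table.gene_ids[idx]}\t{table.scores[idx]:.15g}\t{r}\n")


def read_scores(path) -> GeneScoreTable:
    """Read a table written by :func:`write_scores` (rank order preserved)."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("rank")
    gene_ids = list(df["gene_id"].astype(str))
    scores = df["score"].to_numpy(dtype=float)
    # stored rows are in rank order; rank[r] indexes into that row order
    return GeneScoreTable(gene_ids, scores, rank=np.arange(len(gene_ids)))


def write_expression(data: ExpressionDataset, path, delimiter: str = "\t") -> None:
    """Write a dataset genes-in-rows with identifier row and column."""
    df = pd.DataFrame(data.values, index=list(data.gene_ids),
                      columns=list(data.sample_ids))
    df.to_csv(path, sep=delimiter, float_format="%.15g")
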