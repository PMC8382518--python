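"""Turn the learned projection into gene scores and a selected subset.

A gene's importance is the l2-norm of its row of P: rows the row-sparsity
penalty drove to zero correspond to deselected genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import ExpressionDataset, GeneScoreTable, ValidationError


@dataclass(frozen=True)
class GeneRanking:
    scores: np.ndarray       # per-gene nonnegative importance
    order: np.ndarray        # gene indices, descending score, ties by index
    selected: np.ndarray     # first n_select entries of order

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "order", np.asarray(self.order, dtype=int))
        object.__setattr__(self, "selected", np.asarray(self.selected, dtype=int))

    def rank_of(self) -> np.ndarray:
        """1-based rank of each gene (rank_of()[g] = position of gene g)."""
        ranks = np.empty(self.order.size, dtype=int)
        ranks[self.order] = np.arange(1, self.order.size + 1)
        return ranks


def gene_scores(P: np.ndarray) -> np.ndarray:
    """Per-gene score ||P^i||_2 (row l2-norms of the projection matrix)."""
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValidationError("projection matrix contains non-finite entries")
    return np.linalg.norm(P, axis=1)


def select_top_genes(scores: np.ndarray, n_select: int) -> GeneRanking:
    """Top-``n_select`` genes by score; ties break toward the smaller index."""
    scores = np.asarray(scores, dtype=float)
    m = scores.size
    if not 1 <= n_select <= m:
        raise ValidationError(f"n_select={n_select} must be in [1, {m}]")
    order = np.lexsort((np.arange(m), -scores))
    return GeneRanking(scores=scores, order=order, selected=order[:n_select])


def subset_expression(
    data: ExpressionDataset,
    ranking: GeneRanking,
    keep_original_order: bool = True,
) -> ExpressionDataset:
    """Dataset restricted to the selected genes; samples untouched."""
    idx = ranking.selected
    if idx.size and (idx.min() < 0 or idx.max() >= data.n_genes):
        raise ValidationError("selected gene index out of range")
    if keep_original_order:
        idx = np.sort(idx)
    return ExpressionDataset(
        data.values[idx],
        [data.gene_ids[i] for i in idx],
        data.sample_ids,
        labels=data.labels,
    )


def score_table(data: ExpressionDataset, ranking: GeneRanking) -> GeneScoreTable:
    """Package a ranking as a writable GeneScoreTable."""
    return GeneScoreTable(data.gene_ids, ranking.scores, rank=ranking.order)
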