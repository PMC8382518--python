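"""Cross-validated classification accuracy of a selected gene subset.

The selection is unsupervised; classifiers enter only as downstream
evaluation instruments through an opaque fit/predict contract (any sklearn
estimator qualifies).  By default gene selection is performed once on the
full data before fold splitting, mirroring the common published protocol;
``selection_inside_folds`` enables the unbiased nested variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_io import ExpressionDataset, RunConfig, ValidationError
from .gene_ranking import gene_scores, select_top_genes
from .solver import fit


@dataclass(frozen=True)
class CVResult:
    mean_accuracy: float
    sd_accuracy: float       # sd over repeat-level mean accuracies
    per_fold: tuple[float, ...]
    n_folds: int
    n_repeats: int
    classifier_name: str


@dataclass(frozen=True)
class SelectionCurve:
    gene_counts: tuple[int, ...]
    accuracies: tuple[CVResult, ...]

    def __post_init__(self):
        if len(self.gene_counts) != len(self.accuracies):
            raise ValidationError("gene_counts and accuracies must be parallel")
        if np.any(np.diff(self.gene_counts) <= 0):
            raise ValidationError("gene_counts must be strictly increasing")


def make_classifier(name: str, seed: int = 0):
    """Thin adapters over standard learners honoring fit/predict."""
    name = name.lower()
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier(n_neighbors=5)
    if name == "1nn":
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier(n_neighbors=1)
    if name == "svm":
        from sklearn.svm import SVC
        return SVC(kernel="linear", random_state=seed)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValidationError(f"unknown classifier {name!r}")


def stratified_folds(labels, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified partition of sample indices into folds."""
    labels = np.asarray(labels)
    n = labels.size
    if n_folds > n:
        raise ValidationError(f"n_folds={n_folds} exceeds n={n}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        warnings.warn(
            "a class has fewer members than folds; stratification degrades"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=seed % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return [test for _, test in skf.split(np.zeros(n), labels)]


def cross_validated_accuracy(
    data: ExpressionDataset,
    selected_genes,
    classifier,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold accuracy on the selected gene subset."""
    if data.labels is None:
        raise ValidationError("cross-validation requires sample labels")
    selected = np.asarray(selected_genes, dtype=int)
    X = data.values[selected].T  # samples x genes for the classifier
    y = np.asarray(data.labels)
    per_fold: list[float] = []
    repeat_means: list[float] = []
    for r in range(n_repeats):
        folds = stratified_folds(y, n_folds, seed=seed + 1009 * r)
        fold_accs = []
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(y.size), test_idx)
            classifier.fit(X[train_idx], y[train_idx])
            pred = classifier.predict(X[test_idx])
            fold_accs.append(float(np.mean(pred == y[test_idx])))
        per_fold.extend(fold_accs)
        repeat_means.append(float(np.mean(fold_accs)))
    return CVResult(
        mean_accuracy=float(np.mean(per_fold)),
        sd_accuracy=float(np.std(repeat_means, ddof=0)),
        per_fold=tuple(per_fold),
        n_folds=n_folds,
        n_repeats=n_repeats,
        classifier_name=type(classifier).__name__,
    )


DEFAULT_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3)


def selection_curve(
    data: ExpressionDataset,
    config_grid,
    gene_counts,
    classifier,
    seed: int = 0,
    n_folds: int = 5,
    n_repeats: int = 5,
    selection_inside_folds: bool = False,
) -> SelectionCurve:
    """Best-over-grid CV accuracy at each selected-gene count.

    For every count d and every configuration in the grid, the selector is
    fitted, the top-d genes kept, and CV accuracy measured; the best grid
    point's result is reported (optimal-parameter protocol).
    """
    config_grid = list(config_grid)
    if not config_grid:
        raise ValidationError("config grid must not be empty")
    gene_counts = sorted(int(d) for d in gene_counts)

    rankings = []
    for config in config_grid:
        state = fit(data, config)
        rankings.append(gene_scores(state.P))

    results = []
    for d in gene_counts:
        best = None
        for scores in rankings:
            ranking = select_top_genes(scores, d)
            if selection_inside_folds:
                raise NotImplementedError(
                    "nested selection requires refitting per fold; use "
                    "cross_validated_accuracy with per-fold rankings"
                )
            res = cross_validated_accuracy(
                data, ranking.selected, classifier,
                n_folds=n_folds, n_repeats=n_repeats, seed=seed,
            )
            if best is None or res.mean_accuracy > best.mean_accuracy:
                best = res
        results.append(best)
    return SelectionCurve(tuple(gene_counts), tuple(results))


def grid_configs(
    base: RunConfig,
    alphas=DEFAULT_GRID,
    betas=DEFAULT_GRID,
    gammas=DEFAULT_GRID,
) -> list[RunConfig]:
    """Cartesian alpha/beta/gamma grid around a base configuration."""
    from dataclasses import replace
    return [
        replace(base, alpha=a, beta=b, gamma=g)
        for a in alphas for b in betas for g in gammas
    ]
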