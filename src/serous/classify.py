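"""Signature classification with nested cross-validation.

Decision-tree (DT) and random-forest (RF) classifiers evaluated by
stratified three-fold nested cross-validation: the inner loop grid-searches
``min_samples_split`` and ``max_depth``, the outer loop measures held-out
accuracy.  Also provides the per-gene univariate validation of a signature
(t-test on log-transformed values with direction and fold-change counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .deg import fold_change, ttest_raw
from .io import ExpressionMatrix

DEFAULT_GRID = {
    "min_samples_split": [2, 4, 8, 16],
    "max_depth": [2, 4, 8, None],
}


@dataclass
class CVReport:
    model: str
    outer_fold_accuracies: list[float]
    chosen_params: list[dict]
    seed: int
    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean(self.outer_fold_accuracies))


def _make_estimator(model: str, seed: int, n_estimators: int,
                    criterion: str = "gini"):
    if model == "dt":
        return DecisionTreeClassifier(criterion=criterion, random_state=seed)
    if model == "rf":
        return RandomForestClassifier(n_estimators=n_estimators,
                                      criterion=criterion, random_state=seed,
                                      n_jobs=1)
    raise ValueError(f"unknown model {model!r}; expected 'dt' or 'rf'")


def nested_cv(X, y, model: str = "rf", seed: int = 0, folds: int = 3,
              grid: dict | None = None, n_estimators: int = 500) -> CVReport:
    """Stratified nested cross-validation accuracy of a DT or RF classifier.

    ``X`` is samples x features, ``y`` the class labels.  Per outer fold the
    inner 3-fold grid search (maximizing accuracy) picks
    ``min_samples_split`` / ``max_depth``; the refit model is scored on the
    held-out outer fold, which the grid search never sees.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than "
            f"{folds} folds; reduce the fold count")
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(seed)
    outer = StratifiedKFold(n_splits=folds, shuffle=True,
                            random_state=int(rng.integers(2**31)))
    accs, params = [], []
    for train_idx, test_idx in outer.split(X, y):
        assert not set(train_idx) & set(test_idx)
        inner = StratifiedKFold(n_splits=folds, shuffle=True,
                                random_state=int(rng.integers(2**31)))
        est = _make_estimator(model, int(rng.integers(2**31)), n_estimators)
        search = GridSearchCV(est, grid, scoring="accuracy", cv=inner,
                              n_jobs=1, refit=True)
        search.fit(X[train_idx], y[train_idx])
        accs.append(float(search.score(X[test_idx], y[test_idx])))
        params.append(dict(search.best_params_))
    return CVReport(model=model, outer_fold_accuracies=accs,
                    chosen_params=params, seed=seed)


def nested_cv_matrix(matrix: ExpressionMatrix, signature, model: str = "rf",
                     seed: int = 0, folds: int = 3,
                     n_estimators: int = 500) -> CVReport:
    """Nested CV on an expression matrix restricted to a gene signature,
    with sample group labels as classes."""
    sub = matrix.subset_genes(signature)
    X = sub.values.to_numpy(dtype=float).T
    y = np.array([sub.groups[s] for s in sub.sample_ids])
    return nested_cv(X, y, model=model, seed=seed, folds=folds,
                     n_estimators=n_estimators)


def validate_signature_univariate(matrix: ExpressionMatrix, group_1: str,
                                  group_2: str, signature,
                                  log2_transform: bool = True,
                                  alpha: float = 0.05) -> dict:
    """Per-gene univariate validation of a signature between two groups.

    Each signature gene present in the matrix gets a pooled t-test on
    (optionally) log2(x+1)-transformed values, the direction of change, and
    a signed fold change on the raw means.  Returns a dict with a ``table``
    DataFrame, the ``missing`` genes, and counts of significant genes and of
    genes with |FC| >= 2.
    """
    cols_1 = matrix.samples_in(group_1)
    cols_2 = matrix.samples_in(group_2)
    present = [g for g in signature if g in matrix.values.index]
    missing = [g for g in signature if g not in matrix.values.index]
    rows = []
    for gene in present:
        v1 = matrix.values.loc[gene, cols_1].to_numpy(dtype=float)
        v2 = matrix.values.loc[gene, cols_2].to_numpy(dtype=float)
        t1, t2 = (np.log2(v1 + 1), np.log2(v2 + 1)) if log2_transform else (v1, v2)
        t, df, p = ttest_raw(t1, t2)
        fc = fold_change(float(v1.mean()), float(v2.mean()), pseudocount=0.01)
        rows.append({"gene": gene, "t": t, "df": df, "p": p,
                     "fold_change": fc,
                     "direction": "down" if fc > 0 else "up"})
    table = pd.DataFrame(rows)
    n_sig = int((table["p"] < alpha).sum()) if len(table) else 0
    n_fc2 = int((table["fold_change"].abs() >= 2).sum()) if len(table) else 0
    return {"table": table, "missing": missing,
            "n_significant": n_sig, "n_abs_fc_ge_2": n_fc2}
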