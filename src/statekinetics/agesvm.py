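"""Sparse linear classification of cell age / label status.

An L1-penalized linear support-vector classifier (squared hinge) is
fitted along a grid of regularization strengths C; holdout accuracy per
C traces the accuracy-vs-sparsity path, and marker ("chrono-variant")
genes are the nonzero weights at the smallest C whose accuracy is
within one standard error of the best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


def default_c_grid() -> np.ndarray:
    return np.logspace(-3, 1, 20)


@dataclass
class SparsePath:
    c_values: np.ndarray
    accuracy: np.ndarray
    n_nonzero: np.ndarray
    nonzero_genes: list[list[int]]
    chosen_c: float
    selected_genes: list[int]
    best_accuracy: float
    chosen_accuracy: float


def _split_and_scale(X, y, holdout_frac, seed):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes")
    if counts.min() < 10:
        raise ValueError("each class needs >= 10 cells")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_frac, stratify=y, random_state=seed
    )
    scaler = StandardScaler().fit(X_tr)  # training statistics only
    return scaler.transform(X_tr), scaler.transform(X_te), y_tr, y_te


def fit_sparse_path(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: np.ndarray | None = None,
    holdout_frac: float = 0.2,
    seed: int = 0,
) -> SparsePath:
    """Fit the L1 path and select genes by the one-standard-error rule.

    Per C, a LinearSVC(penalty='l1', loss='squared_hinge') is trained on
    a stratified split standardized with training statistics; the
    selected C is the smallest (sparsest) whose holdout accuracy is
    within 1 SE (binomial, at the best C) of the best accuracy.
    """
    c_grid = np.sort(np.asarray(c_grid if c_grid is not None else default_c_grid()))
    X_tr, X_te, y_tr, y_te = _split_and_scale(X, y, holdout_frac, seed)
    accs = np.empty(len(c_grid))
    nnz = np.empty(len(c_grid), dtype=int)
    gene_lists: list[list[int]] = []
    for i, c in enumerate(c_grid):
        clf = LinearSVC(
            penalty="l1", loss="squared_hinge", dual=False, C=c,
            max_iter=5000, tol=1e-4, random_state=seed,
        )
        clf.fit(X_tr, y_tr)
        accs[i] = (clf.predict(X_te) == y_te).mean()
        genes = np.flatnonzero(np.abs(clf.coef_[0]) > 1e-8)
        nnz[i] = len(genes)
        gene_lists.append(genes.tolist())
    best_i = int(np.argmax(accs))
    se = np.sqrt(accs[best_i] * (1 - accs[best_i]) / len(y_te))
    ok = np.flatnonzero(accs >= accs[best_i] - se)
    chosen_i = int(ok[0])  # smallest C within 1 SE of the best
    return SparsePath(
        c_values=c_grid,
        accuracy=accs,
        n_nonzero=nnz,
        nonzero_genes=gene_lists,
        chosen_c=float(c_grid[chosen_i]),
        selected_genes=gene_lists[chosen_i],
        best_accuracy=float(accs[best_i]),
        chosen_accuracy=float(accs[chosen_i]),
    )


def holdout_accuracy(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, holdout_frac: float = 0.2,
    seed: int = 0,
) -> dict:
    """Single-split stratified holdout accuracy and confusion counts."""
    X_tr, X_te, y_tr, y_te = _split_and_scale(X, y, holdout_frac, seed)
    clf = LinearSVC(
        penalty="l1", loss="squared_hinge", dual=False, C=C,
        max_iter=5000, tol=1e-4, random_state=seed,
    )
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    classes = np.unique(y_te)
    confusion = {
        f"{true}->{p}": int(((y_te == true) & (pred == p)).sum())
        for true in classes
        for p in classes
    }
    return {
        "accuracy": float((pred == y_te).mean()),
        "confusion": confusion,
        "n_test": int(len(y_te)),
    }
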