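"""Deterministic sample partitioning: Kennard-Stone and k-fold CV.

Kennard-Stone picks a representative calibration subset by maximin selection
under Euclidean distance: seed with the two mutually most distant spectra,
then repeatedly add the spectrum whose minimum distance to the selected set
is largest.  The default split assigns 66 % to training; the test set size is
floor(0.34 * N), which on 191 spectra gives the canonical 127/64 partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "kennard_stone", "kfold_indices",
           "write_split_report"]


@dataclass(frozen=True)
class SplitResult:
    """Outcome of a training/test partition."""

    train: np.ndarray
    test: np.ndarray
    algorithm: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        tr, te = set(self.train.tolist()), set(self.test.tolist())
        if tr & te:
            raise ValueError("training and test indices overlap")


def _ks_select(D: np.ndarray, n_train: int, rows: np.ndarray) -> list[int]:
    """Greedy maximin selection on a pairwise-distance matrix.

    Ties break toward the smaller row index (documented, makes the selection
    order invariant to row permutation up to that tie-break).
    """
    n = D.shape[0]
    if n_train < 2:
        raise ValueError("Kennard-Stone needs a training size of at least 2")
    if np.all(D == 0):
        warnings.warn("all pairwise distances are zero; Kennard-Stone falls "
                      "back to row-index order", stacklevel=3)
        return [int(rows[s]) for s in range(n_train)]
    # seed: the two most distant rows (first such pair in row-major order)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    dmin = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_train:
        dmin[selected] = -1.0
        nxt = int(np.argmax(dmin))  # argmax takes the first (lowest index) tie
        selected.append(nxt)
        dmin = np.minimum(dmin, D[nxt])
    return [int(rows[s]) for s in selected]


def kennard_stone(X: np.ndarray, train_fraction: float = 0.66,
                  labels=None) -> SplitResult:
    """Kennard-Stone training/test split of a data matrix.

    Parameters
    ----------
    X
        (I, J) matrix; distances are Euclidean over its columns.  Pass the
        preprocessed, region-restricted spectra a model will actually see.
    train_fraction
        Fraction assigned to training.  The test size is
        floor((1 - train_fraction) * I); training takes the remainder.
    labels
        Optional per-row class labels.  When given, selection is stratified:
        the total test size is apportioned across classes by largest
        remainder of (1 - train_fraction) * n_class, and Kennard-Stone runs
        inside each class, so every class is represented in both sets.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_test = int(np.floor((1.0 - train_fraction) * n))
    n_train = n - n_test

    if labels is None:
        D = squareform(pdist(X))
        train = np.array(sorted(_ks_select(D, n_train, np.arange(n))))
    else:
        labels = np.asarray(labels)
        classes = list(dict.fromkeys(labels.tolist()))  # first-appearance order
        quota = {c: (1.0 - train_fraction) * np.sum(labels == c) for c in classes}
        test_sizes = {c: int(np.floor(q)) for c, q in quota.items()}
        remainder = n_test - sum(test_sizes.values())
        # largest fractional parts get the leftover test slots
        order = sorted(classes, key=lambda c: quota[c] - test_sizes[c],
                       reverse=True)
        for c in order[:remainder]:
            test_sizes[c] += 1
        train_idx = []
        for c in classes:
            rows = np.flatnonzero(labels == c)
            k = len(rows) - test_sizes[c]
            if k < 2:
                raise ValueError(
                    f"class {c!r} has too few rows for a stratified split")
            D = squareform(pdist(X[rows]))
            train_idx.extend(_ks_select(D, k, rows))
        train = np.array(sorted(train_idx))

    mask = np.ones(n, dtype=bool)
    mask[train] = False
    test = np.flatnonzero(mask)
    return SplitResult(train=train, test=test, algorithm="kennard_stone",
                       params={"train_fraction": train_fraction,
                               "stratified": labels is not None,
                               "metric": "euclidean"})


def kfold_indices(n_rows: int, k: int = 7, groups=None,
                  seed: int = 0) -> list[np.ndarray]:
    """Random k-fold partition of row indices, reproducible from ``seed``.

    Folds are disjoint, cover every row and differ in size by at most one.
    With ``groups`` (e.g. sample ids over replicate spectra) whole groups are
    assigned to folds so replicates never straddle a fold boundary.
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        if k > n_rows:
            raise ValueError("k exceeds the number of rows")
        perm = rng.permutation(n_rows)
        return [np.sort(f) for f in np.array_split(perm, k)]
    groups = np.asarray(groups)
    if groups.shape[0] != n_rows:
        raise ValueError("groups must have one entry per row")
    uniq = list(dict.fromkeys(groups.tolist()))
    if k > len(uniq):
        raise ValueError("k exceeds the number of groups")
    perm = rng.permutation(len(uniq))
    folds = [[] for _ in range(k)]
    for fold_slot, gi in enumerate(perm):
        folds[fold_slot % k].append(uniq[gi])
    out = []
    for members in folds:
        rows = np.flatnonzero(np.isin(groups, members))
        out.append(np.sort(rows))
    return out


def write_split_report(split: SplitResult, path, row_ids=None,
                       folds: list[np.ndarray] | None = None) -> None:
    """Write a CSV of (row id, set, fold) describing a partition.

    ``row_ids`` defaults to the row indices; ``folds`` (over training-set
    positions) fills the fold column for training rows.
    """
    import pandas as pd

    n = len(split.train) + len(split.test)
    ids = list(row_ids) if row_ids is not None else list(range(n))
    assignment = {int(r): "train" for r in split.train}
    assignment.update({int(r): "test" for r in split.test})
    fold_of = {}
    if folds is not None:
        for f_index, fold in enumerate(folds):
            for pos in fold:
                fold_of[int(split.train[int(pos)])] = f_index
    frame = pd.DataFrame({
        "row_id": [ids[r] for r in range(n)],
        "set": [assignment[r] for r in range(n)],
        "fold": [fold_of.get(r, "") for r in range(n)],
    })
    frame.to_csv(path, index=False)
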