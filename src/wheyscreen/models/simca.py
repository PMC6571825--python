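"""SIMCA class modelling: one PCA model per class with confidence limits.

Each class is modelled by its own PCA on class-centered spectra.  A new
spectrum is a member of a class when both its score distance (SD) and its
orthogonal distance (OD) fall inside the class's critical limits at
confidence 1 - alpha; its reduced distance to the class is

    d_c = sqrt( (OD / OD_crit)^2 + (SD / SD_crit)^2 )

The assigned label is the member class with the smallest reduced distance,
or "no-class" when no class accepts the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pca import (PcaModel, fit_pca, orthogonal_distance_limit,
                  score_distance_limit)
from .pls import NO_CLASS, ClassPrediction

__all__ = ["SimcaModel", "fit_simca", "classify_simca"]


@dataclass
class ClassModel:
    pca: PcaModel
    sd_crit: float
    od_crit: float


@dataclass
class SimcaModel:
    """Per-class PCA models with 1-alpha critical distance limits."""

    classes: list
    models: dict            # class -> ClassModel
    alpha: float
    components: dict        # class -> A_c

    def reduced_distance(self, X: np.ndarray) -> np.ndarray:
        """(I, n_classes) matrix of reduced distances d_c.

        A noise-free class model has a vanishing orthogonal-distance limit;
        its OD term is then 0 for spectra exactly in the class subspace and
        infinite otherwise.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        D = np.empty((X.shape[0], len(self.classes)))
        for j, c in enumerate(self.classes):
            cm = self.models[c]
            sd = cm.pca.score_distance(X) / cm.sd_crit
            od_raw = cm.pca.orthogonal_distance(X)
            if cm.od_crit > 1e-12:
                od = od_raw / cm.od_crit
            else:
                od = np.where(od_raw <= 1e-8, 0.0, np.inf)
            D[:, j] = np.sqrt(sd * sd + od * od)
        return D

    def membership(self, X: np.ndarray) -> np.ndarray:
        """(I, n_classes) boolean matrix: inside both critical limits."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        M = np.empty((X.shape[0], len(self.classes)), dtype=bool)
        for j, c in enumerate(self.classes):
            cm = self.models[c]
            M[:, j] = ((cm.pca.score_distance(X) <= cm.sd_crit)
                       & (cm.pca.orthogonal_distance(X)
                          <= max(cm.od_crit, 1e-8)))
        return M


def _cv_orthogonal_distances(Xc: np.ndarray, A: int, k: int,
                             seed: int = 0) -> np.ndarray:
    """Held-out orthogonal distances from a k-fold refit of the class PCA.

    Training residuals underestimate the distance of genuinely new spectra
    to the model (strongly so when channels far outnumber class members), so
    the critical limit is calibrated on cross-validated distances instead.
    """
    from ..split import kfold_indices  # local import to avoid cycle
    I = Xc.shape[0]
    folds = kfold_indices(I, k=min(k, I), seed=seed)
    od = np.empty(I)
    for fold in folds:
        train = np.setdiff1d(np.arange(I), fold)
        a = min(A, len(train) - 1)
        pca = fit_pca(Xc[train], a)
        od[fold] = pca.orthogonal_distance(Xc[fold])
    return od


def _class_limits(pca: PcaModel, Xc: np.ndarray, alpha: float,
                  k: int = 7, seed: int = 0) -> ClassModel:
    # membership requires falling inside BOTH limits, so the confidence is
    # Sidak-split between the two distances: each at 1 - (1 - alpha)^(1/2),
    # giving a joint same-class rejection rate of ~alpha
    alpha_each = 1.0 - np.sqrt(1.0 - alpha)
    od_cv = _cv_orthogonal_distances(Xc, pca.n_components, k, seed)
    sd_crit = score_distance_limit(pca, alpha_each)
    od_crit = orthogonal_distance_limit(od_cv, alpha_each)
    scale = float(np.median(np.linalg.norm(Xc - pca.mean, axis=1)))
    od_train_max = float(pca.orthogonal_distance(Xc).max())
    if od_train_max <= 1e-8 * max(scale, 1e-300):
        # noise-free limit: the model reproduces its class exactly, so the
        # Gaussian T^2 envelope is meaningless for the discrete design
        # levels; expand it to cover the calibration cloud and keep a tiny
        # positive residual tolerance for numerically zero distances
        sd_train = pca.score_distance(Xc)
        sd_crit = max(sd_crit, float(sd_train.max()) * (1.0 + 1e-9))
        od_crit = max(od_crit, 1e-8 * scale)
    return ClassModel(pca=pca, sd_crit=sd_crit, od_crit=od_crit)


def _one_class_cv_error(Xc: np.ndarray, X_other: np.ndarray, A: int,
                        alpha: float,
                        folds: list[np.ndarray]) -> tuple[float, float]:
    """Balanced one-class error and its standard error.

    The error is the held-out same-class rejection rate plus the acceptance
    rate of other-class spectra; the standard error combines the binomial
    uncertainties of both rates.
    """
    rej = []
    for fold in folds:
        fold = np.asarray(fold)
        train = np.setdiff1d(np.arange(Xc.shape[0]), fold)
        if len(train) <= A:
            return np.inf, 0.0
        pca = fit_pca(Xc[train], A)
        cm = _class_limits(pca, Xc[train], alpha)
        sd = pca.score_distance(Xc[fold])
        od = pca.orthogonal_distance(Xc[fold])
        rej.extend(((sd > cm.sd_crit) | (od > cm.od_crit)).tolist())
    pca = fit_pca(Xc, A)
    cm = _class_limits(pca, Xc, alpha)
    p_rej, n_rej = float(np.mean(rej)), len(rej)
    var = p_rej * (1 - p_rej) / n_rej
    p_acc = 0.0
    if X_other.shape[0]:
        sd = pca.score_distance(X_other)
        od = pca.orthogonal_distance(X_other)
        p_acc = float(np.mean((sd <= cm.sd_crit) & (od <= cm.od_crit)))
        var += p_acc * (1 - p_acc) / X_other.shape[0]
    return p_rej + p_acc, float(np.sqrt(var))


def fit_simca(X: np.ndarray, labels, components_per_class=None,
              alpha: float = 0.05, folds_per_class: dict | None = None,
              max_components: int = 6, seed: int = 0) -> SimcaModel:
    """Fit one PCA class model per class with critical limits at 1 - alpha.

    ``components_per_class`` may be a dict (class -> A_c) or a sequence in
    sorted-class order.  When absent, each A_c is chosen to minimize the
    cross-validated one-class classification error (same-class rejection +
    other-class acceptance), ties resolved toward the smaller count; folds
    default to min(7, n_c) random folds per class seeded by ``seed``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    thin = [c for c, n in counts.items() if n < 3]
    if thin:
        raise ValueError(f"classes with fewer than 3 training rows: {thin}")

    if components_per_class is not None and not isinstance(components_per_class, dict):
        components_per_class = dict(zip(classes, components_per_class))

    from ..split import kfold_indices  # local import to avoid cycle

    models, chosen = {}, {}
    for c in classes:
        rows = np.flatnonzero(labels == c)
        Xc = X[rows]
        if components_per_class is not None:
            A = int(components_per_class[c])
        else:
            X_other = X[~np.isin(np.arange(X.shape[0]), rows)]
            a_hi = min(max_components, len(rows) - 2, X.shape[1])
            if folds_per_class and c in folds_per_class:
                folds = folds_per_class[c]
            else:
                folds = kfold_indices(len(rows), k=min(7, len(rows)), seed=seed)
            errs = {a: _one_class_cv_error(Xc, X_other, a, alpha, folds)
                    for a in range(1, a_hi + 1)}
            best_a = min(errs, key=lambda a: errs[a][0])
            best, se = errs[best_a]
            # one-standard-error rule: the smallest count whose error is
            # within one SE of the minimum
            A = next(a for a in sorted(errs) if errs[a][0] <= best + se)
        if A > len(rows) - 1:
            raise ValueError(f"class {c!r}: {A} components exceed its size")
        pca = fit_pca(Xc, A)
        models[c] = _class_limits(pca, Xc, alpha, seed=seed)
        chosen[c] = A
    return SimcaModel(classes=classes, models=models, alpha=alpha,
                      components=chosen)


def classify_simca(model: SimcaModel, X: np.ndarray) -> list[ClassPrediction]:
    """Assign each spectrum to the accepting class of smallest reduced distance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != next(iter(model.models.values())).pca.mean.size:
        raise ValueError("spectrum length does not match the fitted models")
    D = model.reduced_distance(X)
    M = model.membership(X)
    out = []
    for d_row, m_row in zip(D, M):
        if m_row.any():
            masked = np.where(m_row, d_row, np.inf)
            label = model.classes[int(np.argmin(masked))]
        else:
            label = NO_CLASS
        out.append(ClassPrediction(
            label=label,
            membership={c: bool(m) for c, m in zip(model.classes, m_row)},
            score={c: float(-d) for c, d in zip(model.classes, d_row)}))
    return out
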