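"""Partial least squares regression (NIPALS) and PLS-DA classification.

One latent-variable extraction loop serves both the single-response
quantification models and the one-hot discriminant models: weights maximize
the X/Y covariance, X is deflated after each component (Y is not), and the
regression coefficient vector is assembled as B = W (P'W)^-1 Q'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PlsModel", "fit_pls", "select_lv", "PlsDaModel", "fit_plsda",
           "predict_plsda", "ClassPrediction"]

NO_CLASS = "no-class"


@dataclass
class PlsModel:
    """Fitted PLS model with A latent variables.

    ``coef`` maps centered X to centered Y; predictions add the means back.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray    # (J, A) NIPALS weight vectors w_a
    x_loadings: np.ndarray  # (J, A) p_a
    y_loadings: np.ndarray  # (M, A) q_a
    scores: np.ndarray     # (I, A) training t_a
    coef: np.ndarray       # (J, M)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError("prediction matrix has the wrong number of channels")
        Y = (X - self.x_mean) @ self.coef + self.y_mean
        return Y[:, 0] if self.y_mean.size == 1 else Y


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int,
            tol: float = 1e-10, max_iter: int = 500) -> PlsModel:
    """NIPALS PLS with X-only deflation.

    ``Y`` may be a vector (PLSR) or an I x M indicator matrix (PLS-DA).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    I, J = X.shape
    if Y.shape[0] != I:
        raise ValueError("X and Y row counts differ")
    if np.allclose(Y.std(axis=0), 0):
        raise ValueError("response has zero variance")
    A = n_components
    if not 1 <= A <= min(I - 1, J):
        raise ValueError(f"n_components must be in 1..min(I-1, J) = {min(I-1, J)}")

    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    E, F = X - x_mean, Y - y_mean
    W = np.zeros((J, A))
    P = np.zeros((J, A))
    Q = np.zeros((Y.shape[1], A))
    T = np.zeros((I, A))
    for a in range(A):
        u = F[:, int(np.argmax(F.var(axis=0)))]
        w = np.zeros(J)
        for _ in range(max_iter):
            w_new = E.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new /= nw
            t = E @ w_new
            tt = t @ t
            if tt == 0:
                break
            q = F.T @ t / tt
            if q @ q == 0:
                break
            u_new = F @ q / (q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        else:
            warnings.warn("NIPALS did not converge for one latent variable")
        t = E @ w
        tt = t @ t
        if tt == 0:
            raise ValueError("degenerate latent variable: zero score vector")
        p = E.T @ t / tt
        q = F.T @ t / tt
        E = E - np.outer(t, p)  # deflate X only
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p, q, t
    R = W @ np.linalg.inv(P.T @ W)
    coef = R @ Q.T
    return PlsModel(x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P,
                    y_loadings=Q, scores=T, coef=coef)


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    d = np.asarray(y_true, float) - np.asarray(y_pred, float)
    return float(np.sqrt(np.mean(d * d)))


def select_lv(X: np.ndarray, y: np.ndarray, candidates, folds,
              tol: float = 0.02) -> tuple[int, dict]:
    """Choose the latent-variable count by cross-validated RMSE.

    Computes RMSECV for every candidate A over the supplied folds and returns
    the smallest A whose RMSECV is within ``(1 + tol)`` of the minimum —
    fewer latent variables are preferred when the curves are not meaningfully
    different.  Also returns the full RMSECV curve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    candidates = sorted(int(a) for a in candidates)
    if not candidates:
        raise ValueError("no candidate component counts given")
    curve = {}
    all_rows = np.arange(X.shape[0])
    for A in candidates:
        sq = []
        for fold in folds:
            fold = np.asarray(fold)
            train = np.setdiff1d(all_rows, fold)
            a_max = min(A, len(train) - 1, X.shape[1])
            model = fit_pls(X[train], y[train], a_max)
            pred = model.predict(X[fold])
            sq.extend((np.atleast_1d(pred) - y[fold]) ** 2)
        curve[A] = float(np.sqrt(np.mean(sq)))
    best = min(curve.values())
    chosen = next(a for a in candidates if curve[a] <= (1.0 + tol) * best)
    return chosen, curve


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class ClassPrediction:
    """Per-spectrum class assignment with per-class evidence.

    ``membership`` maps class name to a boolean (inside the class model /
    above the assignment threshold) and ``score`` to the continuous evidence
    used to rank classes.  ``label`` is the assigned class or ``"no-class"``.
    """

    label: str
    membership: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)


@dataclass
class PlsDaModel:
    """One-hot PLS discriminant model over a fixed class list."""

    classes: list
    pls: PlsModel

    def predict_membership(self, X: np.ndarray) -> np.ndarray:
        """Predicted indicator values, one column per class."""
        return np.atleast_2d(self.pls.predict(X))


def fit_plsda(X: np.ndarray, labels, n_components: int) -> PlsDaModel:
    """Fit PLS-DA: a shared X decomposition against one-hot class indicators."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"classes with fewer than 2 training rows: {thin}")
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return PlsDaModel(classes=classes, pls=fit_pls(X, Y, n_components))


def predict_plsda(model: PlsDaModel, X: np.ndarray,
                  assign_threshold: float = 0.5) -> list[ClassPrediction]:
    """Assign each spectrum to the class of maximal predicted membership.

    A spectrum whose maximum membership falls below ``assign_threshold`` is
    left unassigned (``"no-class"``).  Exact ties go to the lowest class
    index, with a warning.
    """
    M = model.predict_membership(X)
    out = []
    for row in M:
        top = float(np.max(row))
        winners = np.flatnonzero(row == top)
        if len(winners) > 1:
            warnings.warn("tie in PLS-DA membership; assigning the lowest "
                          "class index", stacklevel=2)
        label = model.classes[int(winners[0])] if top >= assign_threshold \
            else NO_CLASS
        out.append(ClassPrediction(
            label=label,
            membership={c: bool(v >= assign_threshold)
                        for c, v in zip(model.classes, row)},
            score={c: float(v) for c, v in zip(model.classes, row)}))
    return out
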