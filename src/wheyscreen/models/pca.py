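"""Principal component analysis core and robust outlier screening.

The PCA is a plain SVD of the mean-centered intensity matrix (no variance
scaling — spectral convention).  Distances of a spectrum to a fitted model
follow the usual class-modelling pair:

* score distance (SD): Hotelling T^2-style Mahalanobis distance in the score
  space, with an F-distribution critical value;
* orthogonal distance (OD): Euclidean norm of the reconstruction residual,
  with a moment-matched scaled chi-square critical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PcaModel", "fit_pca", "robust_pca_outliers"]


@dataclass
class PcaModel:
    """Fitted PCA: mean, orthonormal loadings, per-component score variances."""

    mean: np.ndarray
    loadings: np.ndarray        # (J, A), columns orthonormal
    score_variance: np.ndarray  # (A,), non-increasing
    residual_variance: np.ndarray  # per training row mean squared residual
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.loadings

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X) @ self.loadings.T + self.mean

    def score_distance(self, X: np.ndarray) -> np.ndarray:
        """Hotelling T^2-style distance: sqrt(sum_a t_a^2 / var_a).

        Components with (numerically) zero training variance — requested
        beyond the data rank — are inert rather than infinitely strict.
        """
        T = self.scores(X)
        floor = 1e-12 * max(float(self.score_variance.max()), 1e-300)
        var = np.where(self.score_variance > floor, self.score_variance, np.inf)
        return np.sqrt(np.sum(T * T / var, axis=1))

    def orthogonal_distance(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        R = (X - self.mean) - self.scores(X) @ self.loadings.T
        return np.linalg.norm(R, axis=1)


def fit_pca(X: np.ndarray, n_components: int) -> PcaModel:
    """Fit PCA by SVD of the centered matrix.

    ``n_components`` must satisfy A <= min(I - 1, J).
    """
    X = np.asarray(X, dtype=float)
    I, J = X.shape
    if not 1 <= n_components <= min(I - 1, J):
        raise ValueError(
            f"n_components must be in 1..min(I-1, J) = {min(I - 1, J)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    A = n_components
    loadings = Vt[:A].T
    scores = U[:, :A] * s[:A]
    score_variance = (s[:A] ** 2) / (I - 1)
    resid = Xc - scores @ loadings.T
    residual_variance = np.mean(resid * resid, axis=1)
    return PcaModel(mean=mean, loadings=loadings,
                    score_variance=score_variance,
                    residual_variance=residual_variance, n_samples=I)


def score_distance_limit(model: PcaModel, alpha: float = 0.05) -> float:
    """F-based Hotelling T^2 bound for a new observation, at confidence 1-alpha."""
    I, A = model.n_samples, model.n_components
    if I <= A:
        return np.inf
    f = stats.f.ppf(1.0 - alpha, A, I - A)
    t2 = A * (I * I - 1.0) / (I * (I - A)) * f
    return float(np.sqrt(t2))


def orthogonal_distance_limit(od_train: np.ndarray, alpha: float = 0.05,
                              n_components: int = 0) -> float:
    """Scaled chi-square (moment-matched) bound on the orthogonal distance.

    OD^2 is approximated as g * chi2(h) with g, h matched to the mean and
    variance of the training OD^2 values.  Training residuals underestimate
    out-of-sample ones, so when ``n_components`` is given the squared
    distances carry the usual small-sample correction I / (I - A - 1) before
    moment matching.
    """
    od2 = np.asarray(od_train, dtype=float) ** 2
    I, A = od2.size, n_components
    if A and I > A + 1:
        od2 = od2 * (I / (I - A - 1.0))
    m = od2.mean()
    v = od2.var(ddof=1) if od2.size > 1 else 0.0
    if m <= 0 or v <= 0:
        return float(np.sqrt(m)) if m > 0 else 0.0
    g = v / (2.0 * m)
    h = 2.0 * m * m / v
    return float(np.sqrt(g * stats.chi2.ppf(1.0 - alpha, h)))


def combined_distance(model: PcaModel, X: np.ndarray, sd_crit: float,
                      od_crit: float) -> np.ndarray:
    """Reduced distance sqrt((OD/OD_crit)^2 + (SD/SD_crit)^2)."""
    sd = model.score_distance(X) / sd_crit
    od = model.orthogonal_distance(X) / (od_crit if od_crit > 0 else np.inf)
    return np.sqrt(sd * sd + od * od)


def robust_pca_outliers(X: np.ndarray, n_components: int,
                        threshold: float | None = None,
                        alpha: float = 0.025,
                        n_iter: int = 5) -> np.ndarray:
    """Flag anomalous spectra by a trimmed, iteratively refitted PCA.

    Each round fits PCA on the current clean subset, computes the combined
    reduced distance of every row, and keeps the rows below the fitted
    distance distribution's 1-alpha point before refitting (a trimmed row
    re-enters once the refitted model accounts for it, so the scheme is
    stable on clean data).  The final flags are rows whose combined distance
    exceeds ``threshold``; by default the threshold is the last iteration's
    scaled chi-square 1-alpha bound, floored at twice the median distance:
    a screening step removes clear instrumental artefacts, and a designed
    concentration grid legitimately places samples in the tail of any
    Gaussian bulk model, so only rows inconsistent with the bulk by a
    multiple are treated as anomalies.
    """
    X = np.asarray(X, dtype=float)
    I = X.shape[0]
    if I < 5:
        raise ValueError("need at least 5 spectra for outlier screening")
    keep = np.arange(I)
    d = np.zeros(I)
    cut = np.inf
    model = None
    od_crit = np.inf
    for _ in range(n_iter):
        model = fit_pca(X[keep], min(n_components, len(keep) - 1))
        sd_crit = score_distance_limit(model, alpha)
        od_crit = orthogonal_distance_limit(
            model.orthogonal_distance(X[keep]), alpha,
            n_components=model.n_components)
        d = combined_distance(model, X, sd_crit, od_crit)
        cut = _chi2_tail_threshold(d[keep] ** 2, alpha)
        new_keep = np.flatnonzero(d <= cut)
        if len(new_keep) < max(5, n_components + 2):
            break
        keep = new_keep
    if threshold is not None:
        return np.flatnonzero(d > threshold)
    od_all = model.orthogonal_distance(X)
    scale = float(np.median(np.linalg.norm(X - model.mean, axis=1)))
    if od_crit <= 1e-8 * max(scale, 1e-300):
        # the model reproduces the kept rows exactly (noise-free limit):
        # there is no residual evidence, and score-distance excursions are
        # design structure, so only off-subspace rows can be artefacts
        return np.flatnonzero(od_all > 1e-8 * max(scale, 1e-300))
    return np.flatnonzero(d > max(cut, 2.0 * float(np.median(d))))


def _chi2_tail_threshold(d2: np.ndarray, alpha: float) -> float:
    """1-alpha bound of a scaled chi-square matched to the median and 90th
    percentile of the squared distances.

    Quantile matching is robust to any residual contamination in the tail
    (moment matching is not) and reproduces the empirical spread of the
    clean bulk, so on outlier-free data about alpha of rows exceed the bound.
    """
    from scipy.optimize import brentq
    q50, q90 = np.quantile(d2, [0.5, 0.9])
    if q50 <= 0 or q90 - q50 <= 1e-12 * max(q90, 1.0):
        return np.inf  # degenerate (e.g. noise-free) distances: nothing to flag
    target = q90 / q50

    def gap(h):
        return stats.chi2.ppf(0.9, h) / stats.chi2.ppf(0.5, h) - target

    lo, hi = 0.2, 5000.0
    if gap(hi) > 0:       # empirical tail lighter than any chi-square
        h = hi
    elif gap(lo) < 0:     # heavier than chi-square allows: widest shape
        h = lo
    else:
        h = brentq(gap, lo, hi)
    g = q50 / stats.chi2.ppf(0.5, h)
    return float(np.sqrt(g * stats.chi2.ppf(1.0 - alpha, h)))
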