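"""Spectral pretreatment operators and composable recipes.

Every operator maps an intensity matrix (I x J, shared axis) to a new matrix,
never mutating its input.  The canonical order for a Raman pipeline here is

    despike -> baseline -> sg_smooth -> {snv | msc | derivative} -> crop

Set-level operators (MSC) take their reference from a training set when one
is supplied, so applying a fitted recipe to a test set uses no test-set
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .spectra import SpectrumSet

__all__ = [
    "despike",
    "baseline_correct",
    "sg_smooth",
    "sg_derivative",
    "snv",
    "msc",
    "normalize",
    "crop",
    "Recipe",
    "apply_recipe",
]


def _as_matrix(x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _restore(x: np.ndarray, was_vector: bool) -> np.ndarray:
    return x[0] if was_vector else x


def despike(intensity, z_threshold: float = 8.0, window: int = 7) -> np.ndarray:
    """Remove cosmic-ray spikes by a running-median filter.

    A channel whose residual against the running median exceeds
    ``z_threshold`` modified z-scores (scaled median absolute deviation of
    the residuals) is replaced by the local median; every other channel is
    returned unchanged.
    """
    if window % 2 == 0:
        raise ValueError("despike window must be odd")
    X, vec = _as_matrix(intensity)
    if window >= X.shape[1]:
        raise ValueError("despike window must be shorter than the spectrum")
    out = X.copy()
    for i in range(X.shape[0]):
        med = median_filter(X[i], size=window, mode="nearest")
        resid = X[i] - med
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad == 0:
            continue
        z = 0.6745 * (resid - np.median(resid)) / mad
        bad = np.abs(z) > z_threshold
        out[i, bad] = med[bad]
    return _restore(out, vec)


def baseline_correct(intensity, axis: np.ndarray, order: int = 1,
                     n_iter: int = 10) -> np.ndarray:
    """Subtract a robustly fitted low-order polynomial baseline.

    A degree-``order`` polynomial is fitted by trimmed iterations: fit, keep
    the half of the channels with the smallest residuals, refit (``n_iter``
    rounds).  Peaks only push intensity upward, so the retained half tracks
    the peak-free lower envelope and the corrected spectrum sits near zero
    between bands.
    """
    if order not in (0, 1, 2, 3):
        raise ValueError("baseline order must be in {0, 1, 2, 3}")
    X, vec = _as_matrix(intensity)
    u = np.linspace(-1.0, 1.0, X.shape[1])  # scaled axis for conditioning
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        y = X[i]
        keep = np.ones(y.size, dtype=bool)
        for _ in range(n_iter):
            coef = np.polynomial.polynomial.polyfit(u[keep], y[keep], order)
            base = np.polynomial.polynomial.polyval(u, coef)
            resid = y - base
            cut = np.median(resid)
            keep = resid <= cut
        out[i] = y - base
    return _restore(out, vec)


def sg_smooth(intensity, window: int = 25, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing (polynomial edge handling).

    Interior values of an exact polynomial of degree <= ``polyorder`` are
    preserved to machine precision.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    X, vec = _as_matrix(intensity)
    if window > X.shape[1]:
        raise ValueError("smoothing window longer than the spectrum")
    out = savgol_filter(X, window, polyorder, axis=-1, mode="interp")
    return _restore(out, vec)


def sg_derivative(intensity, axis: np.ndarray, deriv_order: int = 1,
                  window: int = 25, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay derivative with respect to wavenumber.

    The local fitted polynomial is differentiated ``deriv_order`` times and
    scaled by the (uniform) grid spacing, so the output carries units of
    intensity per cm^-1 (or per cm^-2).
    """
    if deriv_order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if polyorder < deriv_order:
        raise ValueError("polyorder must be >= derivative order")
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    delta = float(np.mean(np.diff(axis)))
    X, vec = _as_matrix(intensity)
    out = savgol_filter(X, window, polyorder, deriv=deriv_order, delta=delta,
                        axis=-1, mode="interp")
    return _restore(out, vec)


def snv(intensity) -> np.ndarray:
    """Standard normal variate: per-spectrum standardization to mean 0, sd 1."""
    X, vec = _as_matrix(intensity)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV is undefined for a constant spectrum")
    return _restore((X - mu) / sd, vec)


def msc(intensity, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference (x ~ a + b * ref) and
    returned as (x - a) / b.  The reference defaults to the mean spectrum of
    the input set; when correcting a test set the training reference must be
    passed explicitly.
    """
    X, vec = _as_matrix(intensity)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (X.shape[1],):
        raise ValueError("reference length must match the spectra")
    A = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(A, X.T, rcond=None)  # (2, I): a, b
    a, b = coef[0], coef[1]
    if np.any(b == 0):
        raise ValueError("MSC slope is zero for some spectrum")
    return _restore((X - a[:, None]) / b[:, None], vec)


def normalize(intensity) -> np.ndarray:
    """Unit vector (l2) normalization per spectrum."""
    X, vec = _as_matrix(intensity)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize an all-zero spectrum")
    return _restore(X / norms, vec)


def crop_mask(axis: np.ndarray, regions) -> np.ndarray:
    """Boolean channel mask for a union of inclusive [lo, hi] regions."""
    regions = sorted((float(lo), float(hi)) for lo, hi in regions)
    mask = np.zeros(axis.size, dtype=bool)
    prev_hi = None
    for lo, hi in regions:
        if lo >= hi:
            raise ValueError(f"empty crop region [{lo}, {hi}]")
        if lo < axis[0] or hi > axis[-1]:
            raise ValueError(f"crop region [{lo}, {hi}] outside the axis")
        if prev_hi is not None and lo <= prev_hi:
            raise ValueError("crop regions overlap")
        prev_hi = hi
        mask |= (axis >= lo) & (axis <= hi)
    return mask


def crop(intensity, axis: np.ndarray, regions) -> tuple[np.ndarray, np.ndarray]:
    """Restrict spectra to a union of wavenumber regions (endpoints included).

    Returns ``(cropped_intensity, cropped_axis)``.
    """
    mask = crop_mask(axis, regions)
    X, vec = _as_matrix(intensity)
    return _restore(X[:, mask], vec), axis[mask]


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

_SHORTHAND = {
    "despike": "despike",
    "baseline": "baseline",
    "sg_smooth": "SG",
    "sg_derivative": "der.",
    "snv": "SNV",
    "msc": "MSC",
    "normalize": "norm",
    "crop": "crop",
}


@dataclass(frozen=True)
class Recipe:
    """An ordered list of named pretreatment steps with parameters.

    Each step is ``(name, params_dict)``; ``describe()`` renders the common
    shorthand, e.g. ``"SG + SNV"``.
    """

    steps: tuple = ()

    def __post_init__(self):
        for name, params in self.steps:
            if name not in _SHORTHAND:
                raise ValueError(f"unknown preprocessing step {name!r}")
            if not isinstance(params, dict):
                raise TypeError("step parameters must be a dict")

    @classmethod
    def make(cls, *steps) -> "Recipe":
        """Build from names or (name, params) pairs: Recipe.make("sg_smooth", ("crop", {...}))."""
        norm = []
        for s in steps:
            if isinstance(s, str):
                norm.append((s, {}))
            else:
                name, params = s
                norm.append((name, dict(params)))
        return cls(tuple((n, dict(p)) for n, p in norm))

    def describe(self) -> str:
        shown = [_SHORTHAND[n] for n, p in self.steps
                 if n not in ("despike", "baseline", "crop")]
        # derivative shorthand carries its order
        out = []
        for (name, params), tag in zip(
                [(n, p) for n, p in self.steps
                 if n not in ("despike", "baseline", "crop")], shown):
            if name == "sg_derivative":
                order = params.get("deriv_order", 1)
                tag = f"{'1st' if order == 1 else '2nd'} der."
            out.append(tag)
        return " + ".join(out) if out else "raw"

    def to_config(self) -> list:
        return [{"step": n, **p} for n, p in self.steps]

    @classmethod
    def from_config(cls, entries) -> "Recipe":
        steps = []
        for e in entries:
            e = dict(e)
            steps.append((e.pop("step"), e))
        return cls.make(*steps)


def apply_recipe(sset: SpectrumSet, recipe: Recipe,
                 fit_on: SpectrumSet | None = None) -> SpectrumSet:
    """Apply a recipe's steps in order to a spectrum set.

    ``fit_on`` supplies the training set whose statistics parameterize
    set-level steps (MSC reference): the training set is pushed through the
    same preceding steps and its mean at that stage is the reference, so no
    statistic of ``sset`` itself leaks into the transform.
    """
    X, axis = sset.intensities.copy(), sset.axis
    F = fit_on.intensities.copy() if fit_on is not None else None
    f_axis = fit_on.axis if fit_on is not None else None
    for name, params in recipe.steps:
        if name == "despike":
            X = despike(X, **params)
            if F is not None:
                F = despike(F, **params)
        elif name == "baseline":
            X = baseline_correct(X, axis, **params)
            if F is not None:
                F = baseline_correct(F, f_axis, **params)
        elif name == "sg_smooth":
            X = sg_smooth(X, **params)
            if F is not None:
                F = sg_smooth(F, **params)
        elif name == "sg_derivative":
            X = sg_derivative(X, axis, **params)
            if F is not None:
                F = sg_derivative(F, f_axis, **params)
        elif name == "snv":
            X = snv(X)
            if F is not None:
                F = snv(F)
        elif name == "normalize":
            X = normalize(X)
            if F is not None:
                F = normalize(F)
        elif name == "msc":
            params = dict(params)
            if "reference" not in params:
                params["reference"] = (F.mean(axis=0) if F is not None
                                       else X.mean(axis=0))
            ref = params["reference"]
            X = msc(X, reference=ref)
            if F is not None:
                F = msc(F, reference=ref)
        elif name == "crop":
            X, new_axis = crop(X, axis, **params)
            if F is not None:
                F, _ = crop(F, f_axis, **params)
                f_axis = _
            axis = new_axis
    return SpectrumSet(axis, X, sset.meta)
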