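"""Classification and regression performance statistics, AUC, and LOD/LOQ.

Classification metrics follow the standard one-vs-rest definitions:

    sensitivity = TP / (TP + FN)        specificity = TN / (FP + TN)
    precision   = TP / (TP + FP)        Youden      = sens + spec - 1
    accuracy    = total correct / total assigned (no-class rows included)
    non-error rate = unweighted mean of class sensitivities
    error rate     = 1 - non-error rate

An unassigned ("no-class") prediction counts as a negative assignment for
every class: a false negative for the true class, a true negative elsewhere.

Detection limits use the blank-prediction convention: LOD = 3.3 * SD / S and
LOQ = 10 * SD / S, with SD the standard deviation of predicted concentration
over unadulterated samples and S the slope of the predicted-vs-reference
calibration line; LOQ / LOD = 10 / 3.3 identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models.pls import NO_CLASS, ClassPrediction, PlsModel

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "GlobalMetrics",
    "RegressionMetrics",
    "DetectionLimits",
    "confusion_from_predictions",
    "class_metrics",
    "global_metrics",
    "auc_one_vs_rest",
    "regression_metrics",
    "detection_limits",
]


@dataclass
class ConfusionMatrix:
    """Counts of true class (rows) versus assigned class (columns).

    The last column collects unassigned ("no-class") spectra.  ``counts`` has
    shape (n_classes, n_classes + 1).
    """

    classes: list
    counts: np.ndarray
    set_label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if self.counts.shape != (n, n + 1):
            raise ValueError("counts must be (n_classes, n_classes + 1)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def members(self) -> np.ndarray:
        """Per-class number of true members (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def percent_correct(self) -> dict:
        """Per-class diagonal / members, in percent."""
        out = {}
        for i, c in enumerate(self.classes):
            m = self.counts[i].sum()
            out[c] = 100.0 * self.counts[i, i] / m if m else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.classes) + [NO_CLASS]
        df = pd.DataFrame(self.counts, index=self.classes, columns=cols)
        df.insert(0, "members", self.members)
        return df


def confusion_from_predictions(truth, predictions,
                               classes=None, set_label: str = "") -> ConfusionMatrix:
    """Tabulate a confusion matrix from labels and predictions.

    ``predictions`` may be :class:`ClassPrediction` objects or plain labels;
    ``"no-class"`` is always a legal prediction.
    """
    truth = list(truth)
    pred = [p.label if isinstance(p, ClassPrediction) else p
            for p in predictions]
    if len(truth) != len(pred):
        raise ValueError("truth and predictions differ in length")
    if classes is None:
        classes = sorted(set(truth))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes) + 1), dtype=int)
    for t, p in zip(truth, pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p == NO_CLASS:
            counts[index[t], -1] += 1
        elif p in index:
            counts[index[t], index[p]] += 1
        else:
            raise ValueError(f"unknown predicted label {p!r}")
    return ConfusionMatrix(classes=list(classes), counts=counts,
                           set_label=set_label)


@dataclass
class ClassMetrics:
    """One-vs-rest counts and rates for a single class.

    Rates that would divide by zero are ``None`` (undefined), never 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    youden: float | None
    auc: float | None = None


def _rate(num: int, den: int) -> float | None:
    return num / den if den else None


def class_metrics(cm: ConfusionMatrix, cls) -> ClassMetrics:
    """One-vs-rest metrics for ``cls`` derived from the confusion counts."""
    if cls not in cm.classes:
        raise ValueError(f"class {cls!r} not in the confusion matrix")
    i = cm.classes.index(cls)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum() - tp)          # includes no-class rows
    fp = int(cm.counts[:, i].sum() - tp)
    tn = int(cm.total - tp - fn - fp)
    sens = _rate(tp, tp + fn)
    spec = _rate(tn, fp + tn)
    prec = _rate(tp, tp + fp)
    youden = sens + spec - 1.0 if sens is not None and spec is not None else None
    return ClassMetrics(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens,
                        specificity=spec, precision=prec, youden=youden)


@dataclass
class GlobalMetrics:
    accuracy: float
    non_error_rate: float
    error_rate: float


def global_metrics(cm: ConfusionMatrix) -> GlobalMetrics:
    """Accuracy and (non-)error rate of a whole confusion matrix.

    Accuracy is total correct over all rows (unassigned rows count as
    incorrect); the non-error rate is the unweighted mean of per-class
    sensitivities and the error rate its complement.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm.counts[:, :-1])) / cm.total
    sens = [class_metrics(cm, c).sensitivity for c in cm.classes]
    if any(s is None for s in sens):
        raise ValueError("a class without members has undefined sensitivity")
    ner = float(np.mean(sens))
    return GlobalMetrics(accuracy=accuracy, non_error_rate=ner,
                         error_rate=1.0 - ner)


def auc_one_vs_rest(truth, scores, classes=None) -> dict:
    """Rank-based (Mann-Whitney) one-vs-rest AUC per class, ties averaged.

    ``scores`` is an (I, n_classes) array of continuous class evidence —
    predicted membership for PLS-DA, negative reduced distance for SIMCA —
    or a list of :class:`ClassPrediction` carrying per-class scores.
    """
    truth = np.asarray(list(truth))
    if classes is None:
        classes = sorted(set(truth.tolist()))
    if len(set(truth.tolist())) < 2:
        raise ValueError("AUC needs at least two classes in the truth")
    if isinstance(scores, (list, tuple)) and scores \
            and isinstance(scores[0], ClassPrediction):
        S = np.array([[p.score[c] for c in classes] for p in scores])
    else:
        S = np.asarray(scores, dtype=float)
    if np.any(np.isnan(S)):
        raise ValueError("scores must not be NaN")
    out = {}
    for j, c in enumerate(classes):
        pos = truth == c
        n1, n0 = int(pos.sum()), int((~pos).sum())
        if n1 == 0 or n0 == 0:
            out[c] = None
            continue
        r = rankdata(S[:, j])
        out[c] = float((r[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
    return out


@dataclass
class RegressionMetrics:
    """R^2 and RMSE of one evaluation set, with its sample count."""

    r2: float
    rmse: float
    n: int
    set_tag: str = ""


def regression_metrics(y_ref, y_pred, set_tag: str = "") -> RegressionMetrics:
    """Exact-formula RMSE and R^2 (centered on the evaluated set's mean)."""
    y = np.asarray(y_ref, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_res = float(np.sum((y - p) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: reference values have zero variance")
    return RegressionMetrics(r2=1.0 - ss_res / ss_tot,
                             rmse=float(np.sqrt(ss_res / y.size)),
                             n=y.size, set_tag=set_tag)


@dataclass
class DetectionLimits:
    """Blank-based detection and quantification limits (mass %)."""

    sd_blank: float
    slope: float
    lod: float
    loq: float


def detection_limits(model: PlsModel, blank_spectra: np.ndarray,
                     y_ref, y_pred) -> DetectionLimits:
    """LOD/LOQ from blank predictions and the calibration slope.

    ``blank_spectra`` are >= 3 spectra of unadulterated material on the same
    (preprocessed) channel grid the model was fitted on; the slope S is the
    least-squares slope of predicted vs reference concentration over the
    calibration pairs.
    """
    B = np.atleast_2d(np.asarray(blank_spectra, dtype=float))
    if B.shape[0] < 3:
        raise ValueError("need at least 3 blank spectra")
    preds = np.atleast_1d(model.predict(B))
    sd = float(np.std(preds, ddof=1))
    y = np.asarray(y_ref, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    slope = float(np.polyfit(y, p, 1)[0])
    if slope <= 0:
        raise ValueError("degenerate calibration: non-positive slope")
    return DetectionLimits(sd_blank=sd, slope=slope,
                           lod=3.3 * sd / slope, loq=10.0 * sd / slope)


def as_percent(x: float | None, decimals: int = 1) -> float | None:
    """Express a rate as a percentage at table precision (one decimal)."""
    return None if x is None else round(100.0 * x, decimals)
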