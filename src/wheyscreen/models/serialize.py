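"""Versioned JSON persistence for fitted models.

Arrays are stored as nested lists; every container carries a format version
and whatever provenance the caller supplies (recipe, region, seed, split).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .pca import PcaModel
from .pls import PlsDaModel, PlsModel
from .simca import ClassModel, SimcaModel

__all__ = ["save_model", "load_model"]

FORMAT_VERSION = 1


def _pca_to_dict(m: PcaModel) -> dict:
    return {"mean": m.mean.tolist(), "loadings": m.loadings.tolist(),
            "score_variance": m.score_variance.tolist(),
            "residual_variance": m.residual_variance.tolist(),
            "n_samples": m.n_samples}


def _pca_from_dict(d: dict) -> PcaModel:
    return PcaModel(mean=np.array(d["mean"]),
                    loadings=np.array(d["loadings"]),
                    score_variance=np.array(d["score_variance"]),
                    residual_variance=np.array(d["residual_variance"]),
                    n_samples=int(d["n_samples"]))


def _pls_to_dict(m: PlsModel) -> dict:
    return {"x_mean": m.x_mean.tolist(), "y_mean": m.y_mean.tolist(),
            "weights": m.weights.tolist(), "x_loadings": m.x_loadings.tolist(),
            "y_loadings": m.y_loadings.tolist(), "scores": m.scores.tolist(),
            "coef": m.coef.tolist()}


def _pls_from_dict(d: dict) -> PlsModel:
    return PlsModel(**{k: np.array(v) for k, v in d.items()})


def save_model(model, path, provenance: dict | None = None) -> None:
    """Write a fitted PCA/PLS/PLS-DA/SIMCA model to a JSON file."""
    if isinstance(model, PcaModel):
        payload = {"kind": "pca", "model": _pca_to_dict(model)}
    elif isinstance(model, PlsModel):
        payload = {"kind": "pls", "model": _pls_to_dict(model)}
    elif isinstance(model, PlsDaModel):
        payload = {"kind": "plsda", "classes": model.classes,
                   "model": _pls_to_dict(model.pls)}
    elif isinstance(model, SimcaModel):
        payload = {"kind": "simca", "classes": model.classes,
                   "alpha": model.alpha, "components": model.components,
                   "models": {c: {"pca": _pca_to_dict(cm.pca),
                                  "sd_crit": cm.sd_crit,
                                  "od_crit": cm.od_crit}
                              for c, cm in model.models.items()}}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    payload["format_version"] = FORMAT_VERSION
    payload["provenance"] = provenance or {}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_model(path):
    """Read a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    kind = payload["kind"]
    if kind == "pca":
        return _pca_from_dict(payload["model"])
    if kind == "pls":
        return _pls_from_dict(payload["model"])
    if kind == "plsda":
        return PlsDaModel(classes=payload["classes"],
                          pls=_pls_from_dict(payload["model"]))
    if kind == "simca":
        models = {c: ClassModel(pca=_pca_from_dict(d["pca"]),
                                sd_crit=d["sd_crit"], od_crit=d["od_crit"])
                  for c, d in payload["models"].items()}
        return SimcaModel(classes=payload["classes"], models=models,
                          alpha=payload["alpha"],
                          components={c: int(a) for c, a
                                      in payload["components"].items()})
    raise ValueError(f"unknown model kind {kind!r}")
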