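"""End-to-end experiments: 7-class adulteration screening and quantification.

`run_classification` chains the full screening workflow — generate (or load)
spectra, preprocess, robust outlier screen, Kennard-Stone split, fit SIMCA or
PLS-DA, evaluate both sets.  `run_quantification` builds, per adulterant, the
PLSR calibration for each configured (region, recipe) combination, selecting
the latent-variable count by 7-fold RMSECV, and reports R^2 / RMSE triples
plus blank-based LOD/LOQ.

Everything is deterministic given the config seed; every report embeds the
seed, a config hash and the package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (ConfusionMatrix, as_percent, auc_one_vs_rest,
                       class_metrics, confusion_from_predictions,
                       detection_limits, global_metrics, regression_metrics)
from .models import (classify_simca, fit_plsda, fit_simca, predict_plsda,
                     robust_pca_outliers)
from .models.pls import fit_pls, select_lv
from .preprocess import Recipe, apply_recipe
from .spectra import SpectrumSet
from .split import kennard_stone, kfold_indices
from .synthetic import NoiseSpec, default_library, generate_dataset, standard_design

__all__ = ["ExperimentConfig", "REGIONS", "run_classification",
           "run_quantification", "load_config", "write_report"]

#: named spectral regions (cm^-1) used throughout
REGIONS = {
    "full": ((400.0, 1800.0),),
    "adulterant_window": ((500.0, 1100.0),),
    "glutamine_window": ((800.0, 1000.0), (1300.0, 1500.0)),
}

#: class-model component counts used by default for the 7-class SIMCA screen
DEFAULT_SIMCA_COMPONENTS = {"W": 2, "WC": 5, "WG": 4, "WT": 5,
                            "WCG": 5, "WCT": 4, "WTG": 4}

#: default latent-variable counts per (adulterant, region), overridable by
#: the RMSECV search
DEFAULT_PLSR_LV = {
    ("taurine", "full"): 2, ("glutamine", "full"): 4, ("creatine", "full"): 4,
    ("taurine", "adulterant_window"): 6,
    ("glutamine", "glutamine_window"): 8,
    ("creatine", "adulterant_window"): 6,
}


def _base_recipe() -> list:
    # despike -> first-order baseline -> SG smoothing (order 2, 25 points)
    return [("despike", {}), ("baseline", {"order": 1}),
            ("sg_smooth", {"window": 25, "polyorder": 2})]


@dataclass
class ExperimentConfig:
    """Settings for one experiment run.

    ``recipe_steps`` are the pretreatment steps applied after the common
    despike/baseline/smooth stage and before the region crop; ``region`` is a
    key of :data:`REGIONS` or an explicit list of (lo, hi) pairs.
    """

    seed: int = 0
    model: str = "simca"                      # simca | plsda | plsr
    region: object = "adulterant_window"
    recipe_steps: list = field(default_factory=lambda: [("snv", {})])
    levels: dict | None = None                # design overrides
    noise: dict | None = None                 # NoiseSpec overrides
    spectra_csv: str | None = None            # load instead of generate
    meta_csv: str | None = None
    train_fraction: float = 0.66
    stratify: bool = True
    outlier_components: int = 12
    outlier_alpha: float = 0.025
    simca_components: dict | None = None      # None -> defaults / CV search
    simca_alpha: float = 0.05
    plsda_lv: int = 8
    lv_candidates: tuple = tuple(range(1, 11))
    lv_search: bool = True
    k_folds: int = 7
    out_dir: str | None = None

    def regions(self) -> tuple:
        if isinstance(self.region, str):
            return REGIONS[self.region]
        return tuple((float(lo), float(hi)) for lo, hi in self.region)

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(**(self.noise or {}))

    def hash(self) -> str:
        """Digest of the scientific settings (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "recipe_steps" in raw:
        raw["recipe_steps"] = [(e["step"], {k: v for k, v in e.items()
                                            if k != "step"})
                               for e in raw["recipe_steps"]]
    return ExperimentConfig(**raw)


def _provenance(config: ExperimentConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.hash(),
            "package_version": __version__}


def _acquire(config: ExperimentConfig) -> SpectrumSet:
    if config.spectra_csv is not None:
        return SpectrumSet.from_wide_csv(config.spectra_csv, config.meta_csv)
    design = standard_design(config.levels)
    _, sset = generate_dataset(design, default_library(), config.noise_spec(),
                               seed=config.seed)
    return sset


def _preprocess(config: ExperimentConfig, sset: SpectrumSet,
                fit_on: SpectrumSet | None = None) -> SpectrumSet:
    steps = _base_recipe() + list(config.recipe_steps) \
        + [("crop", {"regions": [list(r) for r in config.regions()]})]
    return apply_recipe(sset, Recipe.make(*steps), fit_on=fit_on)


def _screen_outliers(config: ExperimentConfig,
                     processed: SpectrumSet) -> tuple[SpectrumSet, list[int]]:
    flagged = robust_pca_outliers(processed.intensities,
                                  config.outlier_components,
                                  alpha=config.outlier_alpha)
    keep = np.setdiff1d(np.arange(len(processed)), flagged)
    return processed.subset(keep), [int(i) for i in flagged]


def _confusion_report(cm: ConfusionMatrix, aucs: dict | None = None) -> dict:
    gm = global_metrics(cm)
    per_class = {}
    for c in cm.classes:
        m = class_metrics(cm, c)
        per_class[c] = {
            "members": int(cm.members[cm.classes.index(c)]),
            "sensitivity_pct": as_percent(m.sensitivity),
            "specificity_pct": as_percent(m.specificity),
            "precision_pct": as_percent(m.precision),
            "youden_pct": as_percent(m.youden),
        }
        if aucs is not None:
            per_class[c]["auc"] = (None if aucs[c] is None
                                   else round(aucs[c], 2))
    return {
        "per_class": per_class,
        "accuracy_pct": as_percent(gm.accuracy),
        "non_error_rate_pct": as_percent(gm.non_error_rate),
        "error_rate_pct": as_percent(gm.error_rate),
        "n": cm.total,
    }


def run_classification(config: ExperimentConfig) -> dict:
    """Run the full 7-class screening experiment.

    Returns a report bundle with the training/test confusion matrices, the
    per-class and global statistics, per-class AUC on both sets, the rows
    flagged as outliers, and provenance.  Writes CSV/JSON reports when
    ``config.out_dir`` is set.
    """
    if config.model not in ("simca", "plsda"):
        raise ValueError("classification model must be 'simca' or 'plsda'")
    sset = _acquire(config)
    processed = _preprocess(config, sset)
    processed, flagged = _screen_outliers(config, processed)

    labels = processed.labels()
    split = kennard_stone(processed.intensities, config.train_fraction,
                          labels=labels if config.stratify else None)
    train, test = processed.subset(split.train), processed.subset(split.test)

    if config.model == "simca":
        comps = config.simca_components
        if comps is None and len(set(labels.tolist())) == 7:
            comps = DEFAULT_SIMCA_COMPONENTS
        model = fit_simca(train.intensities, train.labels(),
                          components_per_class=comps,
                          alpha=config.simca_alpha, seed=config.seed)
        pred_train = classify_simca(model, train.intensities)
        pred_test = classify_simca(model, test.intensities)
        components = dict(model.components)
    else:
        model = fit_plsda(train.intensities, train.labels(), config.plsda_lv)
        pred_train = predict_plsda(model, train.intensities)
        pred_test = predict_plsda(model, test.intensities)
        components = {"lv": config.plsda_lv}

    classes = sorted(set(labels.tolist()))
    cm_train = confusion_from_predictions(train.labels(), pred_train,
                                          classes, "training")
    cm_test = confusion_from_predictions(test.labels(), pred_test,
                                         classes, "test")
    auc_train = auc_one_vs_rest(train.labels(), pred_train, classes)
    auc_test = auc_one_vs_rest(test.labels(), pred_test, classes)

    report = {
        "model": config.model,
        "region": config.region if isinstance(config.region, str)
                  else list(config.regions()),
        "recipe": Recipe.make(*(_base_recipe() + list(config.recipe_steps))
                              ).describe(),
        "components": components,
        "outliers_removed": flagged,
        "n_train": len(train), "n_test": len(test),
        "training": _confusion_report(cm_train, auc_train),
        "test": _confusion_report(cm_test, auc_test),
        "provenance": _provenance(config),
    }
    if config.out_dir is not None:
        write_report(report, config.out_dir,
                     confusions={"train": cm_train, "test": cm_test})
    report["_confusion_train"] = cm_train
    report["_confusion_test"] = cm_test
    return report


def _quant_combos(adulterant: str) -> list[dict]:
    """The two (region, recipe) model settings examined per adulterant."""
    specific = {"creatine": "adulterant_window", "taurine": "adulterant_window",
                "glutamine": "glutamine_window"}[adulterant]
    full_steps = {"creatine": [("sg_derivative", {"deriv_order": 1,
                                                  "window": 25, "polyorder": 2})],
                  "taurine": [("snv", {})],
                  "glutamine": [("snv", {})]}[adulterant]
    spec_steps = {"creatine": [("msc", {})], "taurine": [("msc", {})],
                  "glutamine": []}[adulterant]
    return [{"region": "full", "steps": full_steps},
            {"region": specific, "steps": spec_steps}]


def run_quantification(config: ExperimentConfig, adulterant: str,
                       combos: list[dict] | None = None) -> dict:
    """Build PLSR calibrations for one adulterant.

    For each (region, recipe) combination the latent-variable count is chosen
    by 7-fold RMSECV on the training set (smallest count within 2 % of the
    minimum), the model is fitted on the training set and evaluated on the
    test set, and LOD/LOQ are computed from the unadulterated training
    spectra.  Returns a report with one entry per combination.
    """
    if adulterant not in ("creatine", "taurine", "glutamine"):
        raise ValueError(f"unknown adulterant {adulterant!r}")
    sset = _acquire(config)
    combos = combos if combos is not None else _quant_combos(adulterant)

    entries = []
    for combo in combos:
        cfg = ExperimentConfig(**{**asdict(config),
                                  "region": combo["region"],
                                  "recipe_steps": list(combo["steps"]),
                                  "out_dir": None})
        cfg.recipe_steps = list(combo["steps"])
        processed = _preprocess(cfg, sset)
        processed, flagged = _screen_outliers(cfg, processed)
        y = processed.fractions(adulterant)
        labels = processed.labels()
        split = kennard_stone(processed.intensities, cfg.train_fraction,
                              labels=labels if cfg.stratify else None)
        Xtr = processed.intensities[split.train]
        Xte = processed.intensities[split.test]
        ytr, yte = y[split.train], y[split.test]

        folds = kfold_indices(len(split.train), k=cfg.k_folds, seed=cfg.seed)
        if cfg.lv_search:
            lv, curve = select_lv(Xtr, ytr, cfg.lv_candidates, folds)
        else:
            key = (adulterant, combo["region"]) \
                if isinstance(combo["region"], str) else None
            lv = DEFAULT_PLSR_LV.get(key, 6)
            curve = {}
        model = fit_pls(Xtr, ytr, lv)

        cal = regression_metrics(ytr, model.predict(Xtr), "calibration")
        cv_pred = np.empty_like(ytr)
        for fold in folds:
            tr = np.setdiff1d(np.arange(len(ytr)), fold)
            cv_pred[fold] = fit_pls(Xtr[tr], ytr[tr],
                                    min(lv, len(tr) - 1)).predict(Xtr[fold])
        cv = regression_metrics(ytr, cv_pred, "cross-validation")
        pred = regression_metrics(yte, model.predict(Xte), "prediction")

        blanks = Xtr[labels[split.train] == "W"]
        if blanks.shape[0] >= 3:
            dl = detection_limits(model, blanks, ytr, model.predict(Xtr))
            lod, loq = round(dl.lod, 2), round(dl.loq, 2)
            ratio = round(dl.loq / dl.lod, 4) if dl.lod > 0 else None
        else:
            lod = loq = ratio = None
        entries.append({
            "region": combo["region"] if isinstance(combo["region"], str)
                      else [list(r) for r in combo["region"]],
            "pretreatment": Recipe.make(*(_base_recipe() + list(combo["steps"]))
                                        ).describe(),
            "lv": int(lv),
            "rmsecv_curve": {str(k): round(v, 4) for k, v in curve.items()},
            "r2_cal": round(cal.r2, 3), "r2_cv": round(cv.r2, 3),
            "r2_pred": round(pred.r2, 3),
            "rmsec_pct": round(cal.rmse, 2), "rmsecv_pct": round(cv.rmse, 2),
            "rmsep_pct": round(pred.rmse, 2),
            "lod_pct": lod, "loq_pct": loq, "loq_lod_ratio": ratio,
            "n_train": int(len(split.train)), "n_test": int(len(split.test)),
            "outliers_removed": flagged,
        })

    report = {"adulterant": adulterant, "models": entries,
              "provenance": _provenance(config)}
    if config.out_dir is not None:
        write_report(report, config.out_dir, table_name=f"plsr_{adulterant}")
    return report


def write_report(report: dict, out_dir, confusions: dict | None = None,
                 table_name: str | None = None) -> None:
    """Write a report bundle as JSON (plus CSV tables) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(out / "metrics.json", "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if confusions:
        for tag, cm in confusions.items():
            cm.to_frame().to_csv(out / f"confusion_{tag}.csv")
    if table_name and "models" in clean:
        pd.DataFrame(clean["models"]).to_csv(out / f"{table_name}.csv",
                                             index=False)
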