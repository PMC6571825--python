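# wheyscreen

Chemometrics for detecting and quantifying adulterants in whey protein
concentrate (WPC) from 785-nm Raman spectra.

Protein content of sports supplements is certified by total-nitrogen assays
(Kjeldahl/Dumas), which cannot tell protein nitrogen from cheap nitrogen-rich
fillers. Creatine, taurine and L-glutamine are common fillers: they inflate
the apparent protein content and are invisible to the certification assay.
Raman spectroscopy sees them directly — creatine at 828 and 1394 cm⁻¹,
taurine at 528, 736 and 1047 cm⁻¹, glutamine at 856 cm⁻¹ — and multivariate
calibration turns those marker bands into a screening and quantification
instrument. This package implements that workflow end to end for
chemometricians and food-authentication labs:

* **synthetic data** — a generator for labelled 785-nm Raman spectra of the
  7 mixture classes (W, WC, WG, WT, WCG, WCT, WTG): pseudo-Voigt band
  libraries, linear mass mixing, fluorescence-like baseline, shot noise,
  cosmic-ray spikes; the standard design is 32 formulations × 2 copies ×
  3 measurement positions = 192 spectra;
* **preprocessing** — despiking, robust polynomial baseline correction,
  Savitzky–Golay smoothing/derivatives (order 2, 25 points), SNV, MSC, ℓ²
  normalization and region cropping, composable as recipes ("SG + SNV");
* **splitting** — Kennard–Stone maximin selection (66/34, optionally
  stratified per class) and seeded k-fold CV;
* **models** — from-scratch PCA with a robust outlier screen, NIPALS PLS
  regression with RMSECV-based latent-variable selection, one-hot PLS-DA,
  and SIMCA class modelling with 95 %-confidence score/orthogonal distance
  limits;
* **evaluation** — confusion matrices with a no-class column, sensitivity /
  specificity / precision / Youden / accuracy / error rate / AUC, R² and
  RMSE for calibration/CV/prediction, and detection limits
  LOD = 3.3·SD/S, LOQ = 10·SD/S (SD = sd of blank predictions,
  S = calibration slope).

## The models in brief

**SIMCA.** One PCA model per class on class-centered spectra. A spectrum
belongs to class *c* when its score distance (Hotelling T², F-based limit)
and orthogonal residual distance (scaled-χ² limit calibrated on
cross-validated residuals) both fall inside the class's critical values; the
assigned label is the accepting class with the smallest reduced distance
d_c = √((OD/OD_crit)² + (SD/SD_crit)²), or *no-class*.

**PLSR / PLS-DA.** NIPALS latent variables t = Xw maximizing covariance with
the response, X deflated per component, B = W(PᵀW)⁻¹Qᵀ. PLSR regresses mass
fractions; PLS-DA regresses one-hot class indicators and assigns by argmax
membership with a 0.5 floor.

## Worked example

`python examples/03_screen_adulteration_simca.py`:

```
model: SIMCA, region 500-1100 cm^-1, recipe SG + SNV
class-model components: {'W': 2, 'WC': 5, 'WCG': 5, 'WCT': 4, 'WG': 4, 'WT': 5, 'WTG': 4}
outliers removed: 0
split: 127 training / 65 test
 training: accuracy 100.0 %  error rate 0.0 %
     test: accuracy 98.5 %  error rate 3.6 %
```

127/65 is the stratified Kennard–Stone 66/34 split of the 192 synthetic
spectra; the test block's only errors are pure-WPC spectra confused with the
lowest adulteration levels, which sit near the detection limit.
`python examples/04_quantify_adulterants_plsr.py` prints the matching
quantification table; e.g. creatine in its 500–1100 cm⁻¹ window:
R²p 0.996, RMSEP 0.23 %, LOD 0.16 %, LOQ 0.50 % (mass fractions), with
LOQ/LOD ≡ 10/3.3.

The other examples show spectrum generation/export (`01`) and recipe
composition (`02`).

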