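# Methods

## Scope and model of the measurement

The package treats a Raman screening experiment on adulterated whey protein
concentrate (WPC) as a pipeline over an I × J intensity matrix: I spectra on
a shared wavenumber axis of J channels, with per-spectrum metadata (class,
adulterant mass fractions in %, replicate copy, measurement position). All
stages — generation, pretreatment, splitting, modelling, evaluation — are
deterministic functions of their inputs and a seed.

## Synthetic spectra

The generator emulates 785-nm spectra over 400–1800 cm⁻¹ on a uniform
1 cm⁻¹ grid (1401 channels). Each component is a sum of pseudo-Voigt bands
(mixing fraction 0.5; FWHM 9–12 cm⁻¹ for the crystalline adulterants,
18–42 cm⁻¹ for the broad protein bands near 1003, 1250, 1450 and 1660 cm⁻¹,
kept clear of the marker positions). Marker bands: creatine 828 and
1394 cm⁻¹; taurine 528, 736, 1033 and 1047 cm⁻¹; glutamine 856 cm⁻¹, plus
minor secondary bands so the components are not rank-one caricatures.

A mixture spectrum is the linear mass combination
(1 − Σf)·WPC + Σ f_k·component_k, to which are added: a random polynomial
baseline of degree ≤ 2 on the axis rescaled to [−1, 1] (offset 0.5–2.0,
slope ±0.5, curvature ±0.05 — a fluorescence background smooth enough that a
first-order fit removes it, which is the pretreatment the pipeline applies),
additive Gaussian noise of sd 0.012 (≈1 % of the protein-band maximum), and
with probability 0.1 per spectrum a one-channel cosmic spike of amplitude
3–10. The pair-class adulteration levels combine 5–10 % per component —
blends carry each declared adulterant at a quantifiable level; a "blend"
with one component at trace level would belie its own class label and make
the class structure unidentifiable for any class-modelling method. Single
adulterant classes span 1–10 % (5 levels), bracketing the percent-scale
detection limits the quantification stage estimates.

The standard design is 32 formulations (2 pure + 3 × 5 single + 3 × 5 pair),
2 independently noised copies, 3 measurement positions: 192 spectra, 12 of
them pure WPC.

**What the generator does not emulate:** photobleaching kinetics, detector
response, peak shifts with matrix composition, nonlinear band saturation,
and between-batch WPC variability. Passing tests therefore demonstrate that
the chemometric machinery is correct and well-calibrated on data satisfying
its own assumptions — not that a particular real instrument will reach the
same accuracy.

## Pretreatment

Canonical order: despike → baseline → SG smooth → {SNV | MSC | derivative |
ℓ² normalize} → crop. Despiking replaces channels whose residual against a
7-channel running median exceeds 8 modified z-scores (MAD-scaled) by the
local median. Baseline correction fits a degree-≤3 polynomial by trimmed
iterations (fit, keep the lower-residual half of channels, refit; 10
rounds), which tracks the peak-free lower envelope without explicit peak
masking. Savitzky–Golay uses window 25 / order 2 by default with polynomial
edge fitting (exact for polynomials of degree ≤ order, which mirror padding
is not). MSC regresses each spectrum on a reference (training-set mean when
a fitted recipe is applied to new data — no test-set statistic enters the
transform). Crops are inclusive on both endpoints: [500, 1100] on the unit
grid keeps 601 channels, [800, 1000] ∪ [1300, 1500] keeps 402.

## Splitting

Kennard–Stone maximin selection under Euclidean distance on the
preprocessed, region-restricted spectra; ties break to the lower row index,
making the selection permutation-invariant. Test size is floor(0.34·N)
(127/64 on 191 spectra). Stratified mode apportions the test total across
classes by largest remainder of 0.34·n_c and runs the selection per class,
so all 7 classes appear in both sets. CV folds are seeded random partitions
at spectrum level (sizes within 1); a replicate-grouped mode keeps all
spectra of one preparation in the same fold for leakage-free validation
(off by default, matching the spectrum-level convention of the screening
literature).

## PCA, outlier screening

PCA is an SVD of the mean-centered matrix (no variance scaling — spectral
convention; unit-variance scaling would inflate noise channels). Distances
to a model: score distance SD = √(Σ t_a²/λ_a) with the F-based Hotelling
limit for new observations, T²crit = A(I²−1)/(I(I−A))·F₁₋α(A, I−A); and
orthogonal distance OD (residual norm) with a moment-matched scaled-χ²
limit, g·χ²(h), h = 2m²/v from the mean and variance of squared distances.

The robust outlier screen fits PCA (default rank 12 in the pipeline — wide
enough to span the 7-class mean and concentration structure) iteratively:
each round recomputes every row's combined reduced distance
√((SD/SDcrit)² + (OD/ODcrit)²) and keeps rows below the fitted scaled-χ²
1−α point (α = 0.025); trimmed rows may re-enter, so the iteration is
stable on clean data. The final flag threshold is that bound floored at
twice the median distance: a screening step removes clear instrumental
artefacts, and a designed concentration grid legitimately occupies the tail
of any Gaussian bulk model. When the final model is exact (noise-free
data), only off-subspace rows are flaggable. The scaled-χ² shape is
quantile-matched (median and 90th percentile) rather than moment-matched
here, for robustness against contamination of the tail.

## PLS, PLS-DA and latent-variable choice

NIPALS with deflation of X only (tolerance 1e-10, ≤500 iterations per LV);
coefficients B = W(PᵀW)⁻¹Qᵀ. The LV count minimizes 7-fold RMSECV, taking
the smallest count within 2 % of the minimum (parsimony under flat curves).
PLS-DA fits the same decomposition against one-hot indicators; assignment
is argmax predicted membership with a configurable 0.5 floor so *no-class*
is reachable; exact ties go to the lowest class index with a warning.

## SIMCA

One PCA per class on class-centered spectra. Critical limits: the score
limit is the F-based new-observation bound; the orthogonal limit is the
scaled-χ² bound calibrated on k-fold cross-validated orthogonal distances —
training residuals badly underestimate the distance of genuinely new
spectra when channels far outnumber class members, and an uncorrected limit
inverts the between-class distance ranking. Membership requires falling
inside both limits; since two tests are combined, each is taken at
1−(1−α)^(1/2) (Šidák), so the joint same-class rejection rate is ≈ α
(verified at α = 0.05 by simulation against a binomial band). Assignment is
the accepting class of minimal reduced distance, else no-class. An exactly
fitting (noise-free) class model expands its T² envelope to cover the
calibration cloud — Gaussian limits are meaningless for discrete design
levels — and keeps a tiny positive residual tolerance.

Per-class component counts default to (2, 5, 4, 5, 5, 4, 4) for the
canonical 7-class screen; when absent they are chosen per class by
cross-validated one-class error (held-out same-class rejection plus
other-class acceptance) under a one-standard-error parsimony rule.

## Evaluation

One-vs-rest counts treat a no-class assignment as a negative for every
class: a false negative for the true class, a true negative elsewhere —
this keeps row sums equal to member counts and makes the accuracy
denominator include unassigned rows (they are errors). Rates that would
divide by zero are reported as undefined, never as 0. Percentages print at
one decimal. AUC is the rank-based (Mann–Whitney) statistic with averaged
ties, scored on predicted membership (PLS-DA) or negative reduced distance
(SIMCA). Regression metrics evaluate the printed formulas exactly, with the
mean taken over the evaluated set. Detection limits use LOD = 3.3·SD/S,
LOQ = 10·SD/S with SD the sd (ddof 1) of model predictions on unadulterated
training spectra and S the least-squares slope of predicted vs reference
concentration; LOQ/LOD ≡ 10/3.3.

## Pipeline defaults and problem sizes

The screening experiment preprocesses with despike → first-order baseline →
SG(25, 2) → SNV → crop 500–1100 cm⁻¹, screens outliers, splits 66/34
stratified, and fits SIMCA (or PLS-DA with 8 LVs). The quantification
experiment examines, per adulterant, the full region and its
component-specific window (500–1100 cm⁻¹ for creatine and taurine,
800–1000 ∪ 1300–1500 cm⁻¹ for glutamine) with the pretreatments
conventional for each (SG + 1st derivative or SG + SNV full-region;
SG + MSC or SG alone in the specific windows), LV count by RMSECV over
1–10. Tests and the acceptance script run these at the standard 192-spectrum
design size; statistical calibration checks use 1000 simulated spectra.
Reports embed the seed, a hash of the scientific configuration and the
package version; rerunning a configuration reproduces reports byte for
byte.

## Known limitations

The synthetic classes are cleanly separable by construction at the default
noise level, so end-to-end accuracies sit near the top of what a real
screen achieves; the informative checks are the calibration properties
(rejection rates, false-flag rates, detection-limit ratios), not the
headline accuracy. SIMCA limit calibration assumes roughly Gaussian
within-class score spread; heavy-tailed real data would need wider limits.
The robust screen is a stand-in for the (unspecified) commercial
robust-PCA variant; it is documented, parameterized and tested on its own
terms. Baseline correction assumes peaks point upward.
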