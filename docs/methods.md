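# Methods

`ramancellid` implements the analysis chain used to identify live human
lung cell cultures from confocal Raman micro-spectra: per-spectrum
conditioning, photodamage-ratio monitoring across repeated scans,
hyperspectral segmentation of area scans, PCA, and PLS-DA classification
with VIP, ROC and RMSE reporting.  Because no measured spectra are
distributed with the package, a synthetic generator reproduces the
statistical structure the analysis assumes, giving every stage a known
ground truth.

## The forward model (synthetic data)

A cell-class template is a set of vibrational bands on a shared
fingerprint grid (600–1800 cm⁻¹, default 1 cm⁻¹ spacing) plus a smooth
baseline.  The 19 band centers are the discriminatory bands reported for
human lung cell cultures — lipids (718, 1264, 1301, 1440 cm⁻¹), proteins
(641, 1003, 1166, 1239, 1580, 1658, 1674 cm⁻¹), nucleic acids (784, 828,
1316, 1458 cm⁻¹) and carbohydrates (881, 944, 1043, 1085 cm⁻¹).  Bands
default to Lorentzian profiles with FWHM 12 cm⁻¹ (any fixed, documented
lineshape suffices for ground-truth testing; 12 cm⁻¹ is a typical
biological linewidth well above the 3–5 cm⁻¹ instrument resolution).
Amplitudes are relative to the 1003 cm⁻¹ phenylalanine ring-breathing
mode at 1.0.

The five classes share all band centers and differ only in amplitudes:

| class | character | offsets |
|---|---|---|
| A549 | carcinoma, droplet-rich | lipid ×1.40 |
| MRC5 | fibroblast | 784 cm⁻¹ ×1.50, other nucleic ×1.18, lipid ×0.88 |
| ATCC | commercial HBEC | protein ×1.12, carbohydrate ×0.93 |
| LONZA | commercial HBEC | protein ×0.97, carbohydrate ×1.12 |
| PAP243 | in-house HBEC | protein ×0.83, carbohydrate ×1.18, nucleic ×1.24 |

PAP243 is deliberately the most distinct of the three epithelial
cultures, and the two commercial cultures the closest pair, matching the
qualitative structure observed in the original measurements.  These
offsets are the planted effect sizes; they were chosen so that the full
default pipeline lands in the reported performance range (spectrum-level
average sensitivity ≈ 92%, cell-level ≈ 95%, ROC AUC ≈ 0.98, model
complexity selected at 3–8 latent variables with the 5% error target
met).

Variability and noise, per the acquisition design of 30 cells × 10
line-scan points per class (1500 spectra total):

* **Between-cell**: multiplicative lognormal band-amplitude factors drawn
  once per cell, per band, with unit mean and CV 0.10.
* **Within-cell** (point-to-point along the line scan): the same, drawn
  per spectrum, CV 0.06.
* **Baseline**: an order-5 polynomial with positive curvature, scaled per
  cell (lognormal CV 0.10), emulating fluorescence plus substrate/media
  background.
* **Noise**: Gaussian with variance proportional to signal plus a dark
  floor (`noise_scale` 0.01), the CCD shot-noise regime; a purely
  additive model is available.
* **Cosmic rays**: Poisson(0.1) events per spectrum, positive excursions
  1–3 points wide, 10–40× the local noise scale.

What the simulator does **not** model: water/media band structure in the
fingerprint window, resonance effects at 488 nm, instrument drift,
focus-dependent substrate contributions, or correlated band chemistry
(bands vary independently).  Passing tests therefore demonstrate that the
analysis recovers the planted structure under these idealized conditions,
not that real cultures are separable at the same rates.

## Conditioning chain

Per spectrum, in order: despiking, baseline subtraction, Savitzky–Golay
smoothing (width 11, order 3), then cropping to the fingerprint window.

* **Despiking** flags points whose second difference has a modified
  z-score above 8 and replaces runs of ≤ 3 points by linear interpolation
  of the flanking points.  A run of second-difference hits longer than
  the maximum spike width + 2 is band curvature, not a spike, and is left
  alone — this keeps noise-free spectra bitwise unchanged.
* **Baseline** is an iterative clipped polynomial ("ModPoly" style):
  fit an order-5 polynomial, clip the working signal to the pointwise
  minimum of signal and fit, repeat until the fit moves less than 10⁻⁶ of
  the signal range (max 100 iterations).  On spectra with many
  overlapping Lorentzians the summed band tails form a pseudo-continuum
  that a polynomial baseline partly removes: strong, relatively isolated
  markers (1003, 1301, 1440, 1658 cm⁻¹) keep their peak heights within
  5%, while weak bands riding the pedestal lose 10–20%.  This is an
  inherent cost of polynomial baselines, not an implementation artifact,
  and the discriminant analysis (which works on derivatives) is
  insensitive to it.
* **Derivatives** are Savitzky–Golay filters taken with respect to the
  wavenumber coordinate (per cm⁻¹), so results do not depend on the grid
  density.  Edges use polynomial extrapolation of the edge window, never
  reflection padding.
* The PLS-DA recipe is vector normalization, a joint second-derivative/
  smoothing step (SG derivative, width 15, order 3 — one filter both
  smooths and differentiates), and mean centering.  The PCA recipe is
  normalization to unit area under the curve.

## Photodamage monitoring

Peak intensity is the windowed maximum (± 8 cm⁻¹) on the
baseline-corrected spectrum — robust to a few cm⁻¹ of calibration drift
between scans; the package takes no stance on point-value vs integral
definitions beyond this documented choice.  Ratios such as I(1003/1301)
are evaluated on the per-scan mean spectrum and regressed on scan index
by ordinary least squares (a minutes axis may be supplied instead;
slopes are then per minute).  Zero-variance ratio series return slope 0
with R² flagged undefined rather than NaN arithmetic.  Note that for
short series the exact 95% confidence interval uses the Student-t
quantile at n−2 degrees of freedom (2.45 at n = 8), not 1.96; the
reported standard errors are the usual OLS ones.

## Hyperspectral segmentation

"Manhattan analysis" is implemented as L1-distance k-means with
coordinate-wise median centroid updates (the median is the L1-optimal
centroid).  Pixels are preprocessed by a smoothed first derivative
(width 9, order 3), which suppresses the baseline while keeping band
intensities comparable across pixels.  Per-pixel vector normalization is
deliberately **not** part of the default pre-mode: empty background
pixels contain essentially pure noise, and normalizing them to unit
scale scatters them over the feature sphere, destroying the background
cluster.  Initialization is squared-distance-weighted seeding (the
k-means++ rule under L1), which reliably seeds small, chemically
distinct regions such as a few lipid-droplet pixels; the best of 10
seeded restarts is kept, assignments break ties toward the lower cluster
index, and labels are renumbered by descending cluster size so the
largest cluster (background) is always cluster 1.  If a cluster empties,
it receives the currently worst-served pixel, which never increases the
objective.  Cluster spectra are means of the raw pixel spectra;
background subtraction removes cluster 1's mean from the others.

## Chemometrics

PCA is an SVD of the recipe-preprocessed, column-centered matrix with a
deterministic sign convention (the largest-magnitude loading element is
made positive).

PLS-DA uses the SIMPLS algorithm: classes are encoded as indicator
columns, and latent variables are extracted from the successively
deflated cross-product matrix X′Y.  Score vectors are orthonormal,
everything is deterministic, and at full rank the predictions coincide
with ordinary least squares (asserted to 10⁻⁸ in the tests, which also
cross-check the 1-LV case against an independent NIPALS
implementation).  Class assignment is the argmax of the predicted
indicator scores; ties resolve to the first class in the calibration's
class order.  Probabilistic/Bayes-threshold assignment is out of scope.

Validation design: every fourth spectrum (acquisition order) forms the
prediction set; model complexity is selected by venetian-blinds
cross-validation with 10 splits (fold j = rows with index ≡ j mod 10) on
the calibration set.  The "classification error average" is the mean
over classes of (false-negative rate + false-positive rate)/2; the
selected complexity is the smallest whose calibration **and** CV error
both reach the 5% target, falling back to the CV minimizer (flagged)
when none does.  Splitting is by spectrum, not by cell; a cell-grouped
variant can be obtained by averaging first, and the cell-level report
quantifies how much the spectrum-level figures benefit from within-cell
correlation.

Reports: per-class sensitivity, specificity, one-vs-rest Mann–Whitney
AUC (ties ½), and RMSEC/RMSECV/RMSEP computed on the continuous
indicator predictions over the calibration, pooled-CV, and prediction
sets.  At cell level the 10 raw point spectra of each cell are averaged
before preprocessing and the same fitted model predicts the averages;
pooled CV predictions are averaged per cell for RMSECV.  Metrics whose
class is absent from a set are reported as NaN, never fabricated.

VIP scores follow the standard formula
VIP_j = √( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),
with SSY_a the Y sum of squares explained by latent variable a; the mean
of VIP² over wavenumbers is exactly 1, so VIP > 1 marks above-average
discriminatory wavenumbers.

## Determinism and problem sizes

All randomness flows from a single seed fanned out into named
per-stage streams (simulation, map, clustering restarts), so a full run
is byte-reproducible.  The test suite and the acceptance script use the
full default study (1500 spectra × 1201 wavenumbers) for recovery
checks, a 24 × 24 map for segmentation, 200 eight-scan series for
trend-fit coverage, and scaled-down simulations (4–6 cells per class,
2 cm⁻¹ grid) for structural and determinism checks.

## Known limitations

* Polynomial baselines attenuate weak bands on crowded fingerprints
  (see above); derivative-based classification is unaffected, but
  absolute band-height ratios from heavily overlapped regions should be
  treated with caution.
* Venetian-blinds splitting at spectrum level lets spectra from one cell
  appear on both sides of a fold; the cell-level report exists precisely
  to expose the difference.
* The simulator's independence assumptions (band amplitudes, pixels) are
  optimistic; correlated biology would lower effective sample sizes.
* Non-uniform wavenumber axes are carried by the data types, but
  derivative filters use the mean grid step and the chemometrics
  operations require a shared axis; mixed axes are refused rather than
  silently interpolated.
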