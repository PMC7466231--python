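# Methods

This note records the models implemented in `hsicolor`, the conventions and
defaults chosen where the field admits more than one, and what the
synthetic-data tests do and do not demonstrate.

## Data model and calibration

Cubes are stored `(line, pixel, band)`, the natural order of push-broom
acquisition (a moving stage sweeps the sample under the spectrograph slit
at 2.08 mm/s, 0.75 mm/pixel in the emulated instrument). Reflectance
calibration is the standard two-point correction

    R = (R_raw − R_dark) / (R_white − R_dark)

with the white reference a ~99 %-reflectance ceramic tile and the dark
reference a capped lens. References may be full frames or per-band vectors;
both broadcast. The correction is exactly invariant to a common positive
gain on all three inputs. Reflectance outside [0, 1.1] is *retained* — the
out-of-range fraction is logged and stored in provenance — because clipping
at this stage would silently bias derivative pre-treatments; clipping
happens only at map-rendering time.

Cubes travel as an ENVI-style ASCII header + flat binary (interleaves bip/
bil/bsq; wavelengths declared in nm or µm and normalised to nm on read;
payload size validated against the header before reshaping) or as a single
HDF5 file. Both roundtrip bit-exactly for float64 data.

## ROI, segmentation and pre-treatments

Calibration spectra are means over a centred 50 × 50-pixel window (floor
convention when the margin is odd). Pixel segmentation thresholds
reflectance at one band — 690 nm for L\*, 685 nm for a\*/b\* — with a strict
`> 0.05` comparison; band lookup snaps to the nearest grid wavelength
within half a step.

Pre-treatment conventions:

* **SNV** uses the sample (n−1) standard deviation, the common
  chemometrics convention.
* **MSC** regresses each spectrum on a reference (ordinary least squares
  intercept/slope) and returns `(x − â)/b̂`. The reference defaults to the
  calibration-set column mean and is *frozen* into fitted models, so
  validation rows and pixel spectra are corrected against the calibration
  reference, never their own mean.
* **Normalisation** is unit trapezoidal area over the wavelength grid
  (equal-area interpretation); max- and vector-norm variants were
  considered and rejected as defaults since equal area is what makes
  spectra comparable in one plot.
* **Derivatives** are Savitzky–Golay, default window 11 bands (55 nm),
  polynomial order 2 for the first and 3 for the second derivative, scaled
  by the 5 nm step to per-nm units; edges are handled by evaluating the
  edge-window polynomial (`mode="interp"`), preserving the band count.
  These defaults are configurable; derivative filters are exact on
  polynomials up to the fit order, which the tests exploit.

All pre-treatments share a fit/apply interface so that cross-validation can
re-estimate any fitted statistics strictly inside each training fold.

## PLSR

PLS1 by NIPALS with deflation of X and y, convergence 1e−12 or 500
iterations. X and y are mean-centred but not variance-scaled (spectra share
units, so scaling would only amplify noise bands). The component pipeline
is folded into a single coefficient vector

    BW = W (PᵀW)⁻¹ q,   intercept = ȳ − x̄ᵀBW

so prediction is affine and BW doubles as the band-importance measure. At
`n_components = rank(X)` the model provably coincides with OLS, which the
suite checks; component loadings are verified against an independent
power-iteration oracle and against scikit-learn's PLSRegression.

The calibration/validation split draws `round(n·2/3)` samples uniformly at
random with a seed (89 samples → 59 + 30); Kennard–Stone was considered but
a seeded random split was preferred as the neutral default when the
original selection rule is unknown. Cross-validation is leave-one-out by
default (appropriate at n ≈ 60–90), k-fold optional. The optimal component
count is the *smallest* count whose RMSECV is within 2 % of the global
minimum — a parsimony rule; the tolerance is a package choice, configurable.

R² quality bands: < 0.66 insufficient, 0.66–0.81 acceptable for
approximate quantitative prediction, 0.81–0.90 good, > 0.90 excellent.

## Wavelength selection

Bands are ranked by |BW| irrespective of sign, ties broken by ascending
wavelength. Backward elimination proceeds dynamically: candidates are tried
in ascending |BW| of the *current* model (re-ranked after every removal,
matching backward-feature-selection semantics rather than one static
ranking); a candidate is removed if the reduced model's RMSECV stays within
`(1 + tolerance)` of the best RMSECV seen so far, with the component count
of every candidate re-optimised by CV so 7–10-band models are not
over-parameterised. "Does not significantly affect accuracy" is thus
operationalised as a relative RMSECV tolerance, default 5 % — no formal
test is implied by the procedure's description, so the threshold is
explicit and logged. Every trial is recorded in a criterion log, making
runs replayable under the same CV seed.

The published reduced sets for the sausage application (10 bands for L\*,
10 for a\*, 7 for b\* — removal fractions 92.0 %, 92.0 %, 94.4 % of the
125-band grid) ship as constants for map construction; they were selected
on the original 89-image dataset and are not reproducible from synthetic
data, so they are formatting/plumbing fixtures, not selection targets.

## Mapping

Unfold takes masked pixels in row-major order into an (n_pixels × n_IOW)
matrix, prediction is the affine model map, and folding restores spatial
positions. Pre-treatments needing full-spectrum context (derivatives, SNV,
MSC, normalisation) are applied to the complete 125-band pixel spectra
*before* subsetting to the IOW columns — applying a derivative to a
7-band non-uniform subset would change its meaning. Background pixels are
NaN (0 is a valid a\*/b\* value, so no numeric sentinel is safe) and render
in a distinct grey; the colour scale is linear with limits defaulting to
the data range.

## Canonical discriminant analysis

CDA solves `S_B v = λ S_W v` (between- vs within-group scatter) via the
symmetric-definite generalized eigensolver; `min(g−1, p)` functions are
kept. Raw coefficients are scaled so canonical scores have unit pooled
within-group variance (`vᵀ(S_W/(n−g))v = 1`), and standardized coefficients
multiply these by the pooled within-group SDs — SPSS's convention, chosen
so reported coefficient magnitudes are comparable across colour variables;
raw coefficients are also exposed. Signs are fixed by making each
function's largest-magnitude coefficient positive. Per function k the
package reports λ, its share of Σλ, the canonical correlation
√(λ/(1+λ)), Wilks' Λ_k = Π_{i≥k} 1/(1+λ_i), and Bartlett's chi-square
approximation `−(n−1−(p+g)/2)·ln Λ_k` on `(p−k+1)(g−k)` degrees of freedom.

Classification is nearest group centroid in canonical score space with
equal priors — an approximation of linear classification functions that is
exact for balanced groups. ANOVA group comparison uses the omnibus F-test
followed by Tukey HSD, compressed into a compact letter display by a greedy
insert-and-absorb sweep (exact for the three-group setting used here).

## Synthetic data: what it emulates, and what it does not

Scenes place a circular "sample" (radius 0.42·min(h, w)) on a background of
constant reflectance 0.02, cleanly below the 0.05 segmentation threshold.
Endmembers are a gently sloping baseline minus Gaussian absorption bands;
endmember 0 always has a band centred at 680 nm (depth 0.10–0.25, σ
12–20 nm) with no other band in 600–760 nm, guaranteeing a local dip at
680 nm like the oxymyoglobin feature of cooked meat. Abundances are
softmax-transformed smooth random fields (non-negative, summing to 1 per
pixel to 1e−12); true pixel colour is a full-rank linear map of
abundances. Raw counts are encoded as `dark + R·(white − dark)` with mildly
spatially structured reference frames, which makes the calibration
*exactly* invertible — by design, so recovery tests have a well-defined
truth. Sensor noise is i.i.d. Gaussian in reflectance units (default SD
0.005, a typical VNIR noise floor).

Sample sets draw CIELAB colours per treatment group from normal
distributions with the measured means/SDs (control 56.83 ± 5.48 / 6.23 ±
2.42 / 20.26 ± 4.81; treatment 1 50.86 ± 8.90 / 7.09 ± 2.41 / 19.75 ± 4.17;
treatment 2 51.09 ± 8.56 / 5.72 ± 1.74 / 17.66 ± 2.89). Only marginal SDs
are available, so within-group covariance is diagonal — an assumption, and
the main respect in which the simulated colour clouds may differ from the
real ones (real L\*/b\* are typically positively correlated). Spectra are
an affine function of the colour triplet: a meat-like baseline plus one
smooth loading spectrum per channel (broadband for L\*, a 560/680 nm
feature pair for a\*, 450/900 nm features for b\*), plus noise. A single
integer seed drives one `numpy.random.Generator` with documented draw
order, so every generator output is a pure function of (parameters, seed).

Consequences for interpretation: passing recovery tests shows the
*pipeline* is correct (calibration inverts the encoding; PLSR recovers a
linear colour–spectrum link exactly at zero noise; maps reproduce the truth
field), not that real sausage spectra are linear in colour. Scattering
nonlinearity, spatially correlated noise, instrument smile/keystone and
casing-edge effects are all outside the generator. The linear L\* loading
also means second-derivative pre-treatment *removes* most L\* information
from synthetic spectra — unlike on real spectra, where curvature carries
signal — so pre-treatment rankings on synthetic data do not transfer to
real data.

## Problem sizes used in the test suite

Scenes of 40×40–60×60 pixels × 125 bands, sample sets of 15–90 samples,
and 10–20-band toys for the PLSR/selection oracles; backward elimination is
exercised on 12 bands × 40 samples over 20 seeds with 5-fold CV. These
sizes give sub-second individual tests while keeping every statistical
check (noise-SD recovery, chance-level and Bayes-rate classification,
RMSECV ≥ RMSEC majorities) comfortably powered.

## Known limitations

* The elimination search is greedy; it will not undo an early removal that
  later proves informative (no floating step).
* Bartlett's chi-square is asymptotic; p-values at n < ~30 are indicative.
* The compact-letter sweep is exact for ≤ 3 groups but can over-letter for
  many groups with non-transitive significance patterns.
* `evaluate_functions` applied to raw colour triplets with standardized
  coefficients mixes conventions; it is provided because published
  coefficient sets are sometimes used that way, but standardized scores
  should divide by the within-group SDs first.
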