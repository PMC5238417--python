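# Methods

`optimammo` reimplements, end to end, a perturbative analysis chain for
time-domain diffuse optical mammography: from simulated time-resolved
transmittance scans of a compressed breast, through estimation of a
lesion's absorption contrast and its decomposition into tissue
constituents, to two-group cohort statistics and boosted-tree lesion
classification. No patient data are available, so a synthetic-data module
generates every input with the statistical structure the clinical study
reports. This note records the models, the parameter choices, and the
limits of what the synthetic validation demonstrates.

## Forward model

Light propagation in the compressed breast is modelled by the diffusion
approximation for a homogeneous slab with extrapolated boundary
conditions. The time-resolved transmittance for an impulsive pencil beam
is the standard image-source series: an isotropic source at depth
`z0 = 1/musp'`, mirrored across the zero-fluence planes at `-ze` and
`s + ze`, with `ze = 2 A D`, `D = 1/(3 musp')` (absorption-independent
convention) and `A(n)` from the Groenhuis polynomial fit of the internal
diffuse reflectance. Defaults: slab thickness `s = 4 cm` ("mildly
compressed" breast; configurable, never hard-coded), tissue refractive
index `n = 1.4`, hence `v = c/n`. The series is truncated at 10 dipole
pairs per side; the truncation error is below 1e-12 of the peak (tested
against 20 pairs).

Two exact properties anchor the implementation: a homogeneous absorption
shift rescales the curve by `exp(-delta * v * t)` to machine precision,
and each time-domain image term integrates analytically to the
steady-state point-source flux, giving a closed-form continuous-wave
transmittance that the numerical time integral matches to ~1e-6.

A lesion is an absorbing sphere of radius `r` centered mid-slab on the
source-detector line of sight (the equivalent sphere of the maximum
lesion diameter). Its effect enters through the perturbative relation

    T(t) = T0(t) * exp(-delta_mua * l(t)),

where `l(t)` is the mean partial pathlength inside the sphere of photons
detected at time `t`. `l(t)` is computed to first Born order: the time
convolution of the source-to-voxel fluence Green's function with the
voxel-to-detector flux Green's function, integrated over the sphere by a
Gauss-Legendre product rule in spherical coordinates (default 16 nodes
per dimension; order 8-10 is sufficient to ~1e-3 and is used in bulk
pipelines), normalized by the unperturbed transmittance. The construction
recovers `l(t) = v t` exactly when the perturbation fills the slab, which
fixes the normalization. Higher-order perturbation corrections are not
implemented: the first-order kernel placed inside the exponential is the
package's model, and its accuracy is measured, not assumed (below).

Numerical caveat: the convolution is evaluated on the curve's time grid,
and coarse grids bias `l(t)` substantially (24% at 250 ps bins). Kernels
must be computed at TCSPC-like resolution — 10 ps bins leave the window-8
values converged to ~0.5% — and the pipeline does so throughout.

## Monte-Carlo oracle

An independent photon-transport simulation validates the diffusion model:
photons are traced with exponential free paths and isotropic scattering
at `mus = musp'` (the similarity equivalent, adequate for time-resolved
transmittance; a Henyey-Greenstein anisotropic mode is available),
unpolarized Fresnel reflection at the index-mismatched faces, absorption
applied analytically as `exp(-mua v t)` at detection, and per-photon
pathlength accumulation inside an optional sphere. The loop is
numba-compiled; 1e6 photons run in well under a minute.

Measured agreement in the diffusive regime (`musp' * s = 40`):
spatially-integrated curve shape (parabolic peak fit and interpolated
FWHM on 50 ps bins) within 0-3%, converged; the Born `l(t)` against the
MC mean sphere pathlength within ~5% (count-weighted mean over
well-populated bins past the peak) when the comparison kernel is averaged
over the detection disc with diffusion lateral weights. The detection
geometry matters: photons exit across a disc, so the matching kernel
displaces the detection point while the sphere stays on the source axis.

## Measurement emulation and curve processing

The instrument response (460-930 ps FWHM depending on wavelength) is a
unit-area kernel convolved onto model curves; photon counting is Poisson
with a configurable per-pixel budget (default 1e6 counts, a generous but
plausible TCSPC total for 25 ms dwell at 20 MHz repetition).

Average breast properties are estimated by weighted least squares of the
IRF-convolved slab model against the measured curve (convolution-forward
fitting; no deconvolution), with Poisson weights (variance = counts,
floored at one), amplitude profiled analytically, over a range from 80%
of the peak on the rising edge to 1% on the tail (common practice;
configurable). Fits pinned at parameter bounds or failing to converge are
flagged, never returned silently; a curve with no slab broadening (pure
IRF) is rejected this way. Recovery at 1e6 counts: mua within 2%, musp'
within 5%, across 20 seeds (typically well under 1%).

Curves are gated into K = 10 contiguous equal-count time windows; window
8 is the analysis window (late, absorption-sensitive photons). Two
boundary conventions are provided: the greedy cumulative rule (window j
ends at the first bin where the cumulative count reaches j/K of the
total) used throughout the pipeline, and a pro-rata mode that splits the
boundary bin so every window holds exactly total/K counts — the two
differ only by bin granularity on realistic histograms, but only the
split mode can guarantee balance on adversarial spiky curves.

The absorption difference is inverted per window as
`delta_mua = ln(T0_w / T_w) / l_w`, with `l_w` the count-weighted average
of `l(t)` over the window (the gating integrates counts, not
instantaneous flux). With an IRF present, `l(t)` is first smeared
consistently, `l_eff = (IRF * T0 l) / (IRF * T0)` — the mean pathlength
of the photons actually counted at each measured time. Omitting this
biases `delta_mua` low by ~15% at 460 ps FWHM. The inversion is exact to
machine precision for a window-constant kernel and to ~1e-4 for the
physical kernel (exponential averaging across the window).

## Spectral unmixing

`delta_mua` at the seven wavelengths (635-1060 nm) is decomposed into
concentration differences of Hb and HbO2 (uM) and water, lipid and
collagen (mg/cm^3) by unconstrained linear least squares on the Beer law
(7 equations, 5 unknowns). No non-negativity is imposed: the unknowns are
signed differences. A non-negative mode exists for absolute compositions.
Derived quantities: `tHb = Hb + HbO2` (additive for differences too);
`SO2 = HbO2/tHb` is only defined for absolute concentrations and inputs
that look like signed differences are rejected.

The packaged extinction table is a literature-like default (hemoglobin
molar extinctions; pure water, lipid and collagen type I absorption per
unit density), clearly labelled synthetic: every quantitative workflow in
the package is round-trip consistent through this table, and nothing
depends on its absolute accuracy. Its conditioning does control noise
amplification — the pseudo-inverse row norms make lipid the noisiest
constituent (sigma ~6.5 mg/cm^3 at the default photon budget and ROI),
which is why detectable lesion contrasts are tens of mg/cm^3.

## Mapping and lesion quantification

A scan is a 1 mm-pitch grid of curves. The breast mask keeps positions
above a count threshold and retains the largest connected component. The
reference (healthy tissue) curve averages the mask eroded by 10 mm
(configurable), minus an optional explicitly marked exclusion (the known
lesion neighborhood), minus pixels whose window-8 counts deviate more
than 3 MAD from the regional median ("marked inhomogeneities"; the MAD
rule is this package's reading of an unstated clinical practice). A
warning fires if less than half the mask survives.

Maps treat every pixel as a potential on-axis lesion with a default
0.5 cm sphere: window-8 inversion per wavelength, then per-pixel
unmixing; out-of-mask pixels are no-data. Maps are qualitative. Lesion
quantification uses the a priori position and equivalent sphere
(radius = max diameter / 2) over a square lesion area of 5 x 5 mm^2, or
9 x 9 mm^2 for diameters strictly above 15 mm: each area pixel inverts
with the kernel of the known sphere at that pixel's lateral offset,
which removes the partial-volume bias of the on-axis assumption
(residual bias < 1% at high counts; at 1e6 counts/pixel the ROI
composition recovers within 20%, noise-limited). Localization is scored
as the centroid of the above-half-max region of the lightly smoothed
collagen map (robust to the flat top of large lesions); it lands within
1 mm of the planted center on the default phantoms.

## Cohort statistics

Multivariate comparisons of the malignant and benign groups use
permutation tests with the add-one correction
`p = (1 + #{perm >= obs}) / (1 + n_perm)` (never zero), seeded and
reproducible, with complete enumeration available at small n. The mean
test's statistic is the squared Euclidean norm of the group mean
difference. The covariance (Mantel-type) test's statistic is the
Frobenius norm of the group covariance difference, computed after
dividing each feature by its pooled standard deviation — the features
carry different units, and without standardization the statistic is
dominated by whichever column is widest; the raw mode remains available.
These statistic choices are this package's own (the named tests do not
pin them); Euclidean distance profiles to the own-group mean feed a
Mann-Whitney comparison (exact enumeration up to combined n = 20,
tie-corrected normal approximation beyond), and Pearson correlations use
the t-based p-value.

Calibration is verified by simulation: type-I error within the binomial
band at alpha = 0.05 over 1000 null datasets; on the default 45/39
covariance-differing preset the covariance test's power is ~82% while the
mean test stays at alpha — the qualitative signature the pipeline is
meant to reproduce.

## Classification

Discrete AdaBoost with depth-2 CART base learners (scikit-learn trees;
Gini impurity, midpoint thresholds): weights start at 1/N; each round
fits on a weight-proportional bootstrap sample of size N (bagging;
`None` disables it and fits with weights directly), measures the weighted
error on the full sample, sets `c_m = log((1 - err_m)/err_m)` (no 1/2
factor), multiplies misclassified weights by `exp(c_m)` and renormalizes.
Perfect rounds keep a capped finite coefficient (ln ~1.6e15); rounds with
`err_m >= 1/2` are discarded and resampled (up to 25 attempts, then the
loop stops with a warning). The prediction is `sign(sum c_m f_m)`, exact
ties broken to benign and flagged. The weight vector is verified to stay
a probability distribution and the staged training error to respect the
classic bound `prod_m 2 sqrt(err_m (1-err_m))` at every round.

Variable importance is the `c_m`-weighted Gini impurity decrease summed
over trees, normalized to one, averaged across repeated runs for the
ranking. Evaluation repeats the stochastic procedure (default 20 times)
and reports mean +/- SD misclassification, sensitivity (malignant
positive) and specificity in percent plus the pooled-score AUC, computed
as the pairwise concordance probability (identical to the threshold-sweep
ROC area). The default protocol is a per-run 70/30 holdout: out-of-bag
scoring is implemented but demoted to a diagnostic, because OOB
sub-ensembles of a sequential booster lose the stagewise structure and
overstate the error badly (~31% vs ~15% truth on the analytic benchmark).
On a 2000-lesion cohort constructed with a 15% Bayes error the classifier
scores 15-17% held-out misclassification; the benchmark cohort is sized
so split noise does not mask that comparison.

## Synthetic data: what it does and does not show

The cohort generator draws the five composition-difference features from
two Gaussians (a multivariate-t option exists for heavier tails). The
default preset uses identical mean vectors and covariances that differ by
a 3x variance inflation on HbO2 and collagen plus altered
collagen-lipid coupling — so the mean test should not reject and the
covariance test should, mirroring the clinical finding's structure.
Printed clinical coefficients are used as generator anchors, never
claimed as reproduced findings: 45/39 group sizes, healthy-background
collagen-lipid correlation -0.78, malignant delta-collagen/delta-lipid
correlation -0.271 (benign -0.079), and the rarity of preventive
Tamoxifen use (3 of 84). Covariates are plausible, not calibrated: age
truncated-normal 40-75, BMI 18-35, parity 0-4, binary familiarity/OC/TAM.
Feature standard deviations are kept within one order of magnitude so the
Euclidean distance profile is meaningful.

Phantoms are a single homogeneous slab plus one sphere. Real breasts are
heterogeneous (gland/fat structure, vessels, skin), lesions are neither
spherical nor mid-slab, and real extinction spectra differ from the
packaged defaults — so passing phantom round trips demonstrates the
*internal consistency and noise behavior* of the estimator chain, not
clinical accuracy. The clinical performance numbers of the original
study require the undeposited 84-patient cohort and are out of reach by
construction.

## Reproducibility

Every stochastic component — Poisson noise, the Monte-Carlo tracer,
bagging, permutation draws, cohort and phantom generation — takes an
explicit seed and is bit-reproducible. `scripts/acceptance.py` re-derives
the headline validation numbers from scratch at study-scale problem
sizes (1e6 Monte-Carlo photons, 20-seed fit studies, a full 35 x 35 mm
phantom at 1e6 counts/pixel, 1000 null calibration datasets, 250 power
datasets, the 2000-lesion classifier benchmark) in a few minutes on one
CPU.
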