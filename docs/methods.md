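# Methods

This note documents the models and numerical conventions behind
`faecalnirs`: what each stage computes, the choices made where the
standard chemometric literature leaves room, and what the synthetic
study generator does and does not emulate.

## Spectral model and pretreatment

Spectra are absorbance, log(1/R), on a uniform 1100–2498 nm grid with
2 nm steps (700 points), the working range of a scanning monochromator
in reflectance mode. Duplicate scans of a sample are averaged *before*
any mathematical treatment; the averaging order relative to screening
is a convention of this package (the alternative is not materially
different for well-behaved replicates, but fixing it keeps runs
deterministic).

Scatter correction is SNV followed by detrending. SNV centres each
spectrum and scales it to unit sample standard deviation, removing
multiplicative scatter and particle-size baseline offsets; it is exactly
invariant under positive affine transforms of the spectrum. Detrend
subtracts an ordinary-least-squares polynomial in wavelength, degree 2
by default, removing baseline shift and curvilinearity. The polynomial
basis is orthonormalised (QR on a scaled Vandermonde matrix) so the
projection is numerically stable across the full wavelength range.

Derivatives use the four-digit convention `d,g,s1,s2`: a centred boxcar
of width `s1`, then a central gap difference with half-window `g`
(first derivative `y[i+g] − y[i−g]`; second `y[i+g] − 2y[i] + y[i−g]`),
then a second boxcar of width `s2`. Three conventions are fixed here
and documented rather than guessed:

- **Composition order** is scatter correction → derivative
  (`pretreat.order = scatter_first`); the alternative
  `derivative_first` is available as a switch because vendor software
  differs on this point.
- **Smoothing placement** follows the digit order: first smoothing,
  then the gap difference, then the second smoothing.
- **Edges are truncated, never padded**: every stage drops the points
  its window cannot cover and the wavelength grid is shortened by
  `s1//2 + g + s2//2` points per edge. Padding would fabricate data
  that then enters the regression. Even smoothing widths are widened
  to the next odd value (with a warning) to keep the filters centred
  and avoid a wavelength shift.

## Outlier screening (GH)

The population is structured by a covariance PCA (mean-centred, not
autoscaled — all wavelengths share units) of the pretreated spectra,
by default with the same `1,5,5,1` + SNV/DT treatment used for
calibrations. Components are retained up to 99 % cumulative explained
variance, capped at n − 1.

The global Mahalanobis statistic is GH = D²/k, where D² is the
Mahalanobis distance of a sample's k-dimensional score vector from the
training-score centroid, computed with the full training score
covariance (sample covariance, n − 1 denominator). For PCA scores the
covariance is diagonal, so this equals the usual sum of squared
standardised scores, but the full-covariance form makes GH exactly
invariant under rotations of the score basis. Two consequences used as
internal consistency checks: the centroid has GH 0, and the average GH
over the fitting set is exactly (n − 1)/n, essentially 1.

Samples with GH above 3.0 are flagged. Screening is a **single pass**:
the kept set is not re-fitted and re-screened, because iterating the
rule can silently eat into the tail of a clean population. Screening
each presentation form independently is the default; since planted
anomalies in the synthetic study are sample-level, both forms flag the
same samples in practice.

## Modified PLS

The calibration engine is single-response NIPALS PLS. Each factor
takes the weight vector `w = E'f/‖E'f‖` (exact in one pass for a single
response), scores `t = Ew`, loadings `p = E't/t't`, `q = f't/t't`, and
deflates `E ← E − tp'`, `f ← f − qt`. The *modified* variant divides
every column of the deflated `E` by its standard deviation before the
next factor; the per-factor scale vectors are stored and replayed at
prediction, so the full predictor remains affine in the input spectrum
(an explicit coefficient vector is recovered by propagating the unit
basis through the recursion).

Numerical conventions:

- The residual standardisation uses the **population SD** (divide by
  n). The modification is described in the literature only
  qualitatively; the denominator is this package's documented choice
  and is recorded in the serialised model, so predictions are
  reproducible either way.
- Columns whose residual SD falls below 10⁻¹² of the largest are left
  unscaled, and factor extraction stops early (with a warning) once
  the total residual X-variance falls below 10⁻¹² of its initial
  value: continuing would amplify round-off through the division.
- y is centred, never autoscaled — reference units (g/kg, MJ/kg,
  digestibility fractions) are meaningful.
- With standardisation off the algorithm is classical PLS1 and is
  tested against an independently coded NIPALS loop and against
  scikit-learn's implementation; on full-rank problems it converges to
  the ordinary-least-squares solution as the factor count approaches
  the rank.

## Cross-validation statistics

Two schemes: a single random partition into four groups whose sizes
differ by at most one (223 samples split 56/56/56/55), and
leave-one-out. For k = 1..15 (the conventional cap for faeces
calibrations) PRESS_k is accumulated by refitting on each fold's
training set; the factor count is fixed across folds within a pass.
The selected k* minimises SECV(k) = sqrt(PRESS_k/n); a one-standard-
error parsimony rule is available as an option but the global minimum
is the default, since the cap already limits complexity.

Definitions: SEC = sqrt(SSE/(n − k* − 1)) on the full-data fit,
R²c = 1 − SSE/SST, SECV = sqrt(PRESS/n), R²cv = 1 − PRESS/SST,
RPD = SD/SECV with SD the n − 1 sample standard deviation of the
reference values. R²cv is reported as computed and can be negative on
pathological data; nothing is clipped. The random-group scheme is one
partition per evaluation (a `repeats`-style average can be had by
looping over seeds; the tests verify that the seed-averaged four-group
SECV tracks the leave-one-out SECV on well-conditioned data).

Treatment search evaluates each of the eight standard codes and keeps
the smallest SECV, breaking ties towards fewer factors, then towards a
first derivative, then towards the earlier code in the list.

Accuracy bands combine R²cv and RPD: excellent (RPD ≥ 3, R²cv ≥ 0.90),
good (RPD 2–3, R²cv 0.70–0.89), moderate (RPD 1.5–2, R²cv 0.50–0.69),
poor below. Exact boundary values are assigned upward (RPD = 3.0 is
excellent). When the two criteria disagree the weaker band is reported
with a discordance flag rather than averaging them away.

## Digestibility

ATTD = 1 − (N_faeces/N_feed)·(AIA_feed/AIA_faeces), with nutrient
concentrations on a dry-matter basis and native acid-insoluble ash as
the marker. The DM coefficient itself uses the g/kg DM contents with
the same marker ratio — the bookkeeping convention is this package's,
documented here because published descriptions rarely spell it out.
Coefficients outside [0, 1] are flagged, not clipped. Concentrations
above 1000 g/kg warn (calculated OM can legitimately exceed 1000 g/kg
DM by a small margin) and above 1100 g/kg are rejected.

## Fisher SECV comparison

F = SECV²(larger)/SECV²(smaller) ≥ 1, compared with the upper (1 − P)
quantile of the F distribution with (n_larger − 1, n_smaller − 1)
degrees of freedom, P = 0.05 by default, where n counts the
cross-validated samples of each model. For two 223-sample models the
critical value is 1.2477, printed as 1.25. Decisions are computed
before rounding; tables print F at two decimals. No multiple-testing
correction is applied across constituents — comparisons are reported
one at a time, mirroring common practice in calibration studies, and
readers should treat the family-wise error accordingly.

## Synthetic study generator

The generator emulates the design such calibrations are developed on:
two batches of 20 pens (four pens per diet across five diets: control,
low/high crude protein, low/high net energy), one floor sample per pen
per day for six days — 240 samples — with 10 removed as freeze-dryer
losses and 7 planted spectral outliers among the 230 survivors, so a
GH screen that catches them leaves 223 calibration samples.

**Chemistry.** Each faecal constituent is drawn from a truncated
normal per (diet, batch). The parent mean and SD are *calibrated by
root-finding* so the realised truncated moments equal the per-diet
targets; truncation at the tabulated minima/maxima (roughly ±2 SD)
would otherwise shrink the realised SD by about 10 %. Where a target
SD is numerically unreachable (it approaches the uniform-distribution
limit (max − min)/√12) a near-flat parent is used and the small
shortfall accepted. A configurable symmetric batch shift (default
±0.125 SD) separates the two batches without moving the totals.

**Marker consistency.** One anchor coefficient — DM digestibility — is
drawn per sample; the faecal AIA concentration is back-solved from it,
and the other four ATTD coefficients follow from the marker equation
with the drawn faecal chemistry and a fixed per-diet feed composition.
Re-applying the ATTD equation to the emitted records therefore
reproduces every coefficient to machine precision. This construction
also reproduces the target ATTD dispersions naturally — the anchor's
variability propagates through the shared marker ratio — and induces
the expected negative correlation between a faecal concentration and
its own digestibility. The feed concentrations are back-computed from
the chemistry and ATTD means (feed AIA fixed at 10 g/kg DM, feed DM at
its analysed per-diet value), since feed GE and the marker levels are
not otherwise pinned down; they are emitted with the bundle so the
round-trip is checkable.

**Spectra.** Absorbance is a Beer–Lambert mixture: each constituent
contributes Gaussian bands at standard NIR assignments (N–H near
2055/2180 nm for protein, C–H near 1725/2310 nm for fat, O–H at
1450/1940 nm for residual moisture = 1000 − DM, broad fibre-like bands
for organic matter, C–H-like bands for gross energy), scaled by its
concentration. Each scan gets a log-normal multiplicative scatter
factor (σ = 0.06 for ground, 0.12 for not-ground samples — the
particle-size effect), a linear baseline with per-scan variation
(twice as variable for not-ground), and i.i.d. instrument noise
(σ = 3·10⁻⁴ absorbance). Two replicate scans are generated per sample.
Planted outliers receive a contamination band (amplitude 0.15 at a
random centre), a curved baseline and a four-fold scatter sigma; a
purely multiplicative anomaly would be removed exactly by SNV and
detrend, so a detectable outlier must carry a shape anomaly.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: laboratory reference error (reference
values are the exact concentrations mixed into the spectra, so
synthetic R²cv values run higher than the ~0.9 typical of real faecal
crude protein), non-linear detector response and wavelength-dependent
pathlength effects, day/pen autocorrelation within a diet, and any
real covariance structure between constituents beyond what the marker
relation induces. The generator is a test harness for the statistical
machinery, not a radiative-transfer model.

## Problem sizes and determinism

Every stochastic step takes an explicit seed (NumPy `SeedSequence`
children for the bundle's sub-streams), and reruns are byte-identical.
The default study (230 samples × 700 wavelengths, two forms, duplicate
scans) generates in well under a second; a leave-one-out evaluation of
a 15-factor calibration on 223 samples takes a few seconds. The test
suite uses the default study for the end-to-end properties and small
(20–60 sample) problems for oracle comparisons, keeping brute-force
refit loops exact rather than sampled.

## Known limitations

- MPLS standardisation applies to X-residuals only; whether vendor
  implementations also rescale y-residuals between factors is not
  publicly specified. The one-factor model is identical either way.
- SECV uses a fixed factor count across folds; software that re-selects
  the factor count inside each fold will differ in the third decimal.
- JCAMP-DX support covers plain tabular `(X++(Y..Y))` records only.
- The Fisher comparison treats the two SECVs as independent variance
  estimates; for two forms scanned on the *same* samples this is
  conservative about correlation, as is conventional for this test.
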