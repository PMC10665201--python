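# Methods

## The osmotic model

Vapour-pressure osmometers report osmolality (mOsm kg⁻¹). For dilute, ideal
solutes this is linear in concentration — van't Hoff's law, −Ψπ = iCRT, with
*i* the dissociation factor — but concentrated macromolecular solutions
depart from linearity because their hydration layers structure an appreciable
fraction of the solvent. We model this with

    −Ψπ(C) = A·C / (1 − I_eff·C)

where `A` (mOsm kg⁻¹ per concentration unit) is the ideal slope and `I_eff`
(per concentration unit) the effective solute–water interaction: the model
has a pole at C = 1/I_eff, where nominally all solvent is structured, and
reduces exactly to the linear law at I_eff = 0. The model is fitted in
instrument units; `osmolality_to_pressure` converts readings to pascals via
Π = c·ρ_w·R·T (ρ_w = 1000 kg m⁻³, R = 8.314 J mol⁻¹ K⁻¹) when energy units
are needed.

### Fitting

`fit_nonideal` pools all points of all replicate curves at one temperature
and fits a single shared (A, I_eff) by bounded nonlinear least squares
(scipy `curve_fit`; A > 0, 0 ≤ I_eff < 1/C_max). Initialization: A from the
slope of the two lowest concentrations, I_eff from 0, with bounded restarts
at I_eff ∈ {0.5, 0.9}/C_max on failure; relative function tolerance 1e-10.

Weighting default is **relative least squares**: one unweighted pass, then
one pass weighted by the fitted curve. Vapour-pressure readings carry noise
roughly proportional to the reading, and readings along one curve span more
than an order of magnitude; under that noise model unweighted covariance
intervals are badly anti-conservative (in our simulations the nominal 95%
intervals covered the truth ~74–86% of the time, versus ~93–96% with relative
weighting). `weighting="none"` and `weighting="sem"` are available.

Confidence intervals: 95% from the residual-scaled covariance with a
t-quantile (dof = n − 2) by default; a seeded nonparametric bootstrap over
curves (default 1000 resamples) as an option. On noise-free input the
covariance collapses, so CIs degenerate to the point estimate; tests treat
"zero within CI" up to solver tolerance (1e-8) in that case.

`ieff_temperature_profile` simply fits each temperature independently and
returns the table ordered by temperature — A is *not* shared across
temperatures, since the ideal slope itself is temperature-dependent.

### Additivity deviation

For an a:b co-solution at total concentration C, the ideal-additivity
prediction is the sum of each component's measured osmolality at its
in-mixture concentration (linear interpolation on the component's own
dilution curve; extrapolation beyond the measured range is an error).
Propagated uncertainty is √(sem_a² + sem_b²). The deviation per point is
100·(predicted − observed)/predicted, so positive deviation means the
observed osmolality fell short of additivity — free water released. The
summary statistic is the mean per-point deviation above a configurable
concentration floor; points with non-positive prediction are excluded and
flagged.

### Dilution buffering index

For an extract dilution series (fractions d ∈ (0, 1], neat = 1.0), a least
squares line through the points with d ≤ d_lin (default 0.3) is extrapolated
to d = 1; the index is (extrapolated − observed_neat)/extrapolated. A
perfectly linear curve gives 0; a buffered (sub-linear) extract gives a
positive index. The statistic is a ratio, hence invariant to rescaling all
readings. d_lin = 0.3 is a default, not an estimate: the linear regime of a
real extract should be confirmed by inspection and d_lin raised or lowered
accordingly (fewer than two points below d_lin is an error instructing the
user to raise it).

## Mixing calculators

Shock recipes assume volume additivity and ideality: mixed osmolarity is the
volume-weighted mean Σvᵢoᵢ/Σvᵢ, and mixed temperature the
heat-capacity-weighted mean Σmᵢcᵢtᵢ/Σmᵢcᵢ (m in kg, c in kJ kg⁻¹ °C⁻¹,
t in °C). Both are permutation-invariant and bounded by their inputs. The
API keeps full precision; the CLI rounds deltas to the nearest mOsm for
display. No activity coefficients, heat losses or buffering chemistry are
modelled.

## Condensation image metrics

**Condensation ratio** (Fourier space). The image is mean-subtracted,
zero-padded to a square FFT grid, and the fraction of spectral power at
radius > 6 px (from the centred origin of the padded spectrum) is reported.
Mean subtraction puts any constant offset into the DC term, which is excluded
from the total, so the ratio is offset-invariant; it is scale-invariant
because numerator and denominator scale together. Padding default: next
power of two ≥ 1.7× the largest dimension, which maps the instrument's
600×600 frames to a 1024×1024 spectrum; radii and the 6-px cutoff are
measured in pixels of that padded spectrum, and ring profiles use half-open
[r, r+3) rings. A uniform image has no non-DC power: the ratio is undefined
and raises by default (`blank_policy="zero"` returns a flagged 0 instead).

**Granulosity index** (real space). A circular high-pass Fourier mask
(radius ≤ cutoff zeroed, DC included) is applied to the
background-subtracted image; the index is the standard deviation of the
filtered signal within the ROI divided by the ROI mean of the
background-subtracted original. The naive "mean of the high-pass-filtered
signal" is ~0 by construction (DC removed), so the original-image ROI mean
is the denominator that yields a well-defined, scale-invariant,
coefficient-of-variation-like statistic. Background defaults to the median
intensity outside the ROI. Because it is computed in real space the index
can be restricted to an ROI (e.g. a segmented nucleus), which the Fourier
ratio cannot.

**Cortical ratio.** The cortical band is the cell mask minus its erosion by
the band width (default 3 px); the ratio is median(band)/median(interior)
after subtracting the median intensity outside the mask. Median statistics
make it robust to puncta and noise; background subtraction makes it
offset-invariant.

**Nuclear segmentation fallback.** Otsu threshold → hole fill → connected
components ≥ a minimum area (default 64 px). Touching nuclei merge into one
component — a documented limitation; the deep-learning segmentations used
for real data are out of scope here.

Coordinates are row-major with origin top-left; masks are boolean and
inclusive. Images must be ≥ 16 px on a side; ROIs need ≥ 32 foreground
pixels for the metrics to be meaningful.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the analyses consume, with known ground
truth; all are deterministic given (spec, seed), with per-replicate
substreams derived from the seed.

* **Osmometry** (`gen_osmometry_series`): readings on the non-ideal curve
  with multiplicative Gaussian noise, default 1% of the reading with 3
  replicates over 8 concentrations (50–400) at A = 1, I_eff = 0.002 —
  instrument-like conditions; per-point sems come from the replicate spread.
  Optionally I_eff falls linearly with temperature to emulate hydration
  growth in the cold.
* **Condensing co-solutions** (`gen_condensing_mixture`): an ideal solute
  (slope 1) plus a macromolecule (A = 1, I_eff = 0.002) mixed 2:1. A
  logistic condensed fraction φ of the *applied* (additive) osmolality —
  onset 700 mOsm kg⁻¹, steepness 0.01 per mOsm kg⁻¹ — removes
  `hydration_release_frac` (default 0.5) of the macromolecule's non-ideal
  excess A·C·I_eff·C/(1 − I_eff·C). Driving φ with the additive rather than
  the observed osmolality keeps the model single-valued; a self-consistent
  closure is bistable once the released term is large. Observed never
  exceeds additive. This is a minimal fixture of the water-release idea, not
  a thermodynamic model.
* **Buffered dilutions** (`gen_buffered_dilution`): the same model along a
  dilution series. The buffered fixture uses full release
  (`hydration_release_frac=1`, I_eff = 0.0025) so the neat reading drops to
  the linear term and falls below the dilute-regime extrapolation; note that
  with partial release and a strongly non-ideal macromolecule the curve's
  own convexity dominates and the index is negative — the index measures
  departure from the *linear* expectation, in either direction. The ideal
  reference (I_eff = 0) is exactly linear.
* **Puncta images** (`gen_puncta_image`): a fraction f of a conserved total
  intensity (conservation exact to machine precision pre-noise/offset) is
  moved from a smooth wide-Gaussian diffuse field (σ = size/4) into
  `n_puncta` Gaussian spots (σ = 3 px), plus a constant offset and Poisson
  (default) or Gaussian noise. The smooth envelope matters: it concentrates
  the uncondensed image's power in the lowest-frequency rings, as the
  cell-scale intensity profile of a real frame does; a perfectly flat field
  would leave shot noise as the only non-DC power and break the metric's
  monotonicity in f. Graded series use a fixed seed family — the same
  per-image seed at every f level — so each image family traces a smooth
  curve in f and medians inherit monotonicity.
* **Cells, nuclei, protein sets**: a disk cell with a painted rim at a known
  rim/interior ratio; non-touching bright ellipses with ground-truth masks;
  protein sets drawn with sampling weights `enrichment_factor` for members
  of the first set (factor 1 → independent).

What passing these tests does *not* show: the generators have no optical
PSF, no 3-D structure, no drift or bleaching, no real extract composition,
and the water-release model is phenomenological — agreement on synthetic
data validates the estimators' correctness and calibration, not the
biological conclusions one would draw from real measurements.

## Statistics

Fisher's exact test on the 2×2 overlap table (overlap, a-only, b-only,
neither; two-sided by summation of tables with probability ≤ observed),
cross-checked in tests against exhaustive hypergeometric enumeration. The
one-proportion z-test uses z = (k/n − p₀)/√(p₀(1−p₀)/n) with a two-sided
normal p and no continuity correction. Benjamini–Hochberg adjustment is the
standard step-up; note BH adjustment is order-preserving and bounded but not
idempotent. Under the null the discrete Fisher p is conservative
(super-uniform), so calibration is asserted as a rejection rate ≤ nominal,
not as uniformity.

## Problem sizes and numerical choices

Test and validation suites run the graded image series at 256² (padded to
512, per the padding rule) with 10 images per level at 10 levels, the
Monte-Carlo fit study at 200 simulations of 3×8-point curves, the Fisher
cross-check over all 2×2 tables with total ≤ 40, and the z-test calibration
at 10,000 null replicates of n = 1000 — sizes chosen so the whole suite
completes in about a minute while leaving the statistics well away from
their thresholds. The 600² → 1024 padding default is exercised on single
images. Degenerate inputs (uniform images, blank ROIs, poles, empty
segmentations) raise typed errors or return documented flagged values rather
than propagating NaNs.
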