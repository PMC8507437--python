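# Methods

## The alignment problem

Two satellite sensors observe the same lake pixel minutes apart.  The
reference sensor (a dedicated 300 m ocean-colour imager, `olci` in the
tables) has narrow, well-validated bands; the test sensor (a 10–60 m
land imager resampled to 300 m, `msi`) has fewer, broader bands and a less
certain atmospheric correction, particularly in the blue–green.  Applying
the same retrieval algorithm to both therefore yields systematically
different chlorophyll-a and turbidity, and the package's job is to retune
the test sensor's algorithm coefficients so its products agree with the
reference over a globally diverse set of lakes.

The alignment target is *consistency between sensors*, not accuracy against
in-situ truth: the reference sensor's product is taken as the response
variable throughout.

## Retrieval models

* **OC2 / OC3**: `log10 chla = a0 + a1·x + a2·x² + a3·x³ + a4·x⁴` with
  `x = log10(Rw490/Rw560)` (OC3: `max(Rw443,Rw490)` in the numerator).  All
  logarithms are base 10.  Valid in clear water (roughly 0.2–10 mg m⁻³);
  turbid or CDOM-rich water aliases into false high chl-a, which is why the
  filter gates demand low reference turbidity.
* **Gilerson-style NIR:red**: `chla = (a·x + b)^c`, `x = Rw708/Rw665`.  The
  coefficient `b` is stored signed (published set `(35.75, −19.30, 1.124)`),
  so the code's `a·x + b` reproduces the published `35.75x − 19.30` form.
  Defined only where the base is positive; elsewhere the product is missing
  with a counted reason.
* **Gons05**: semi-analytical; backscatter is inverted from NIR reflectance
  as `b_b = k_s·aw779·Rw779/(k_γ − k_s·Rw779)` with `k_s = 0.6`,
  `k_γ = 0.082`, then
  `chla = [ (Rw708/Rw665)·(aw709 + b_b) − aw665 − b_b^p ] / a*_chl`.
  Only `p` and `a*_chl` are tuned; the pure-water absorptions are fixed
  configuration defaulting to `aw665 = 0.40`, `aw709 = 0.70`,
  `aw779 = 2.71 m⁻¹` (standard literature values; every result carries the
  set used).  Negative chl-a is returned as computed and handled by the
  range gates, not silently clipped.
* **Nechad turbidity**: `T = A·Rw/(1 − Rw/C)` per band, in FNU.  The A/C
  constants are band-specific look-up values that must be supplied by the
  user; the bundled `nechad_synthetic.json` set is a fixture with realistic
  magnitudes for testing and simulation, not a calibration.
* **Linear calibrations**: `y = gain·x + offset`, used both for the
  turbidity products and for rescaling the test sensor's blue-green log
  ratio onto the reference sensor's ratio scale (shipped set
  `gain 1.442, offset −0.51`), after which the *reference* polynomial is
  applied — the cheap alternative to retuning the polynomial.

Scalar calls raise on domain violations; bulk (table) calls return missing
values with enumerated reason codes, because a million-row table must never
die on one bad pixel.  Scalar and vectorized paths share the same ufunc
calls and agree bit-for-bit.

## Filter cascade

Steps, in fixed order, each accounted in a telescoping report:

1. test-sensor pixel flags (any cloud/cirrus/shadow/land raised, or the
   clear-water flag absent);
2. any reflectance > 1 on either sensor;
3. atmospheric-correction out-of-bounds flag on either sensor;
4. reference-sensor snow/ice flag;
5. fewer than 5 valid neighbours in the 3×3 macro-pixel;
6. trim to the central 99.9% of each sensor's product distribution
   (a row survives only if kept under both sensors' trims);
7. remove test-sensor products more than 2 sample standard deviations from
   the mean (strict inequality; zero variance keeps everything);
8. per-algorithm validity gates: OC2/OC3 keep reference chl-a in
   (0.2, 10) mg m⁻³, reference 708 nm turbidity < 0.5 FNU and positive band
   ratios on both sensors; Gilerson keeps positive test ratio, test chl-a in
   (0, 250) and reference chl-a in (2, 200); Gons05 keeps test chl-a in
   (0, 250) and reference chl-a in (2, 200); turbidity keeps both sensors'
   turbidity positive.  The test sensor's chl-a is deliberately *not*
   range-filtered for OC2/OC3, since it is the tuning response variable.

Numerical choices.  The step-6 percentiles use Hazen plotting positions:
this removes exactly `floor(0.0005·n)` values per tail on large distinct
samples (9,990 of 10,000 retained — the central 99.9%), leaves the tails
empty below n = 1,000, and never removes more than `ceil(0.0005·n)` per
tail.  Steps 6–7 operate on the product of the algorithm being tuned,
computed with the *initial* coefficients over the whole dataset (not per
lake), so trimming cannot see the tuning outcome.  Re-applying the cascade
to its own output is a no-op when the surviving values are tied or
clustered (the planted-violation fixtures used in tests); on continuous
data the data-dependent steps 6–7 can trim a further ~0.1%, which is
inherent to any quantile/σ screen and is documented rather than patched.

## Tuning

`fit_once` minimises `Σ ρ(r_i²)` with `r_i = f(x_i; θ) − y_i`, `ρ` the
Cauchy loss at scale `loss_scale` (default 1.0 in the residual's units),
using scipy's trust-region-reflective solver, unbounded, with
ftol = xtol = 1e-8 and at most 1,000 function evaluations.  Residuals can be
formed in linear product units (default) or in log10 (`objective_space`);
the shipped experiment configurations fit the chl-a algorithms in log10
space — the OCx model is a polynomial *in* log space, and fitting there
keeps the ill-conditioned quartic from being whipsawed by the heavy upper
tail of the concentration distribution — while gain/offset turbidity
calibrations are always fit in linear FNU.

`bootstrap_tune` implements the equal-lake-weight scheme: lakes with fewer
than `min_unique_per_lake = 140` unique (pixel, timestamp) matchups are
excluded and listed; each of `n_replicates` replicates draws
`n_per_lake = 150` rows with replacement from every included lake, refits
from the initial coefficients, and the per-parameter **median** of the
replicate samples is the tuned set (IQR/min/max are reported alongside).
Draws use one root `SeedSequence` spawning a substream per replicate, and
the input table is ordering-normalised (sorted by lake, timestamp,
position) before index assignment, so results are bit-reproducible from the
seed regardless of input row order.  Non-converged replicates are dropped
and counted, never fatal.  Gons05 tuning optimises `(p, a*_chl)` only, with
the water-absorption constants frozen.

`per_lake_tune` fits each lake separately without bootstrap (no size bias
to remove) and reports mean/sd/min/median/max per parameter.
`fit_linear_scaling` is ordinary least squares of y on x.
`coefficient_deviation` reports element-wise tuned/initial multipliers,
with zero initials flagged as undefined.

Default replicate count is 10,000 (the full-campaign setting); the test
suite and the acceptance script use 25–200 replicates, which this package
treats as its standard desk-scale configuration — the bootstrap median of a
5-parameter fit stabilises well below 200 replicates at these data sizes.

## Evaluation

With `x` the test product and `y` the reference product:
`MAD = mean|x−y|`, `MAPD = 100·mean(|x−y|/y)` (rows with `y = 0` excluded
and counted), `RMSD = sqrt(mean (x−y)²)`, `bias = mean(x−y)`, Pearson `R`,
and percentiles of the residual `x − y` under the same quantile convention
as the filter.  The regression slope is OLS of x on y in log10 space for
chl-a (matching how chl-a scatter is conventionally displayed) and linear
space for turbidity.  `RMSD² = bias² + var(residual)` (population variance)
holds as an identity and is asserted in tests.  Welch's t-test is two-sided
with α = 0.05 by default; two degenerate samples with equal means give
p = 1 by convention.  Optical water types are assigned by minimum spectral
angle `arccos(⟨s,r⟩/‖s‖‖r‖)` against user-supplied reference spectra
(scale-invariant; the bundled 13-class CSV is synthetic, for tests only).

## Synthetic matchup generator

`generate_dataset` emulates a two-year multi-lake campaign:

* **Truth**: per-lake log-normal chl-a (scenario medians span 0.4–40
  mg m⁻³, σ_log 0.7) and turbidity; distance to land log-uniform on
  [0.1, 100] km.  The default 24-lake scenario pairs the largest
  observation counts (46 up to 20,000 per lake, echoing the heavy skew of
  real archives at desk scale) with the clearest water, and calibrates the
  turbidity–trophic relation (`T_med = clip(1.8·chla_med^0.9, 0.15, 15)`,
  σ_log 1.4) so ~80% of all records fall below 5 FNU.
* **Reference reflectances** are built by *exact inversion* of the
  retrieval formulas: the blue-green log ratio by bracketed Newton inversion
  of the OCx quartic on its monotone branch (default x ∈ [−0.35, 1.5];
  round-trips to < 1e-9), the NIR:red ratio by the closed-form Gilerson
  inverse (or the Gons05 inverse when configured), and the red/NIR
  amplitudes by the closed-form Nechad inverse of the turbidity truth.
  Chl-a outside the OCx branch image is clamped to it by default (OCx
  saturation in eutrophic water); a resample-with-budget mode is available.
* **Test-sensor reflectances** derive from the reference through configured
  near-linear ratio distortions plus Gaussian ratio noise (the scenario
  default blue-green distortion is the inverse of the shipped rescaling
  `y = 1.442x − 0.51`, so refitting recovers that line), per-band NIR
  amplitude gains (defaults are the inverses of the shipped turbidity
  calibration gains), a positively-skewed log-normal factor on the
  blue-green bands, multiplicative reflectance noise, and an additive
  adjacency perturbation `amplitude·exp(−d/5 km)·N(0,1)` per band.
* **Contamination**: independent Bernoulli quality flags and a configured
  macro-pixel neighbour-count distribution.

What the generator does *not* emulate: radiative transfer, spectral
band-pass differences, spatially correlated flags or adjacency, sun glint,
or any coupling between atmospheric state and water type.  Passing tests
therefore demonstrate that the pipeline's statistics and estimators behave
correctly under the assumed distributional structure — not that the shipped
tuned coefficients are optimal for any real sensor pair.

## Problem sizes

The default scenario generates ~81k matchups (scaled in tests to 4–40k);
recovery experiments use 16 lakes × 1,000 records with 200 bootstrap
replicates; the Monte-Carlo check of the turbidity skew uses the full ~81k
scenario.  These sizes are the package's standard configuration and run in
seconds to a few tens of seconds on one CPU.

## Known limitations

* The equal-lake-weight bootstrap median is a coefficient-space aggregate;
  for strongly nonlinear models the median coefficient vector is not the
  median *predictor*, and for the OCx quartic the replicate spread on the
  high-order terms is enormous (IQRs of tens), faithfully reflecting the
  instability of retuning high-order empirical polynomials.
* The linear-space objective can make OC2 retuning degrade MAD on small
  campaigns; the log-space objective is the recommended setting for chl-a.
* MAPD is undefined at zero reference values and asymmetric by
  construction; compare it only between runs using the same reference.
* The synthetic generator's flag contamination is spatially independent, so
  it cannot exercise flag-adjacency interactions.
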