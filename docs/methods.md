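# Methods

This note documents the statistical model behind each stage of the
pipeline, the parameters that matter, the design choices made where the
literature leaves the procedure open, and what the synthetic-data
generators do and do not emulate.

## Time, space and units

Ages are calendar years BP (present = AD 1950); ages after 1950 are
negative. Charcoal concentration is particles cm⁻³ and CHAR particles
cm⁻² yr⁻¹; biomass is t ha⁻¹; population density inhabitants km⁻²;
temperature anomalies °C and precipitation anomalies percent change
against the pre-industrial state. Distances are haversine distances on
a sphere of radius 6371 km, boundary-inclusive; grids are cell-centred
and site-to-pixel distance is measured to cell centres, with no
partial-pixel area weighting (pixels are small relative to the 100-km
buffers). The buffer area uses exact πr², not a rounded value.

## Age-depth models

Records carry dated control points (depth, age), strictly monotone in
both coordinates. Ages between controls are interpolated piecewise
linearly; extrapolation beyond the dated interval is refused rather
than guessed. Linear interpolation is the minimal defensible choice
when the original age-model method of each archived record is unknown;
anything smoother would manufacture precision the data do not carry.

## Charcoal standardisation

CHAR magnitudes differ across records by orders of magnitude for
analytical rather than ecological reasons, so each record passes
through minmax → Box-Cox → Z-score before any pooling:

* **minmax** maps the record onto [0, 1]; constant records are
  excluded with a warning (they carry no within-record signal).
* **Box-Cox** y = ((x+ε)^λ − 1)/λ (log for λ = 0) homogenises the
  within-record variance. ε = 0.01 is added first because minmax maps
  the record minimum to exactly 0 and zero charcoal counts are common;
  λ is fitted per record by maximising the profile log-likelihood over
  a grid on [−2, 2] with step 0.01 (the likelihood is computed in
  closed form, vectorised over the grid; `scipy.stats.boxcox_llf`
  serves as the independent oracle in the tests). Both ε and the grid
  are configurable.
* **Z-score** uses the sample standard deviation (n − 1).

The chain is exactly invariant to rescaling a record's concentrations
by any positive constant: minmax removes the scale before the λ fit,
so the refit is bit-identical. This invariance is asserted in the test
suite.

## Binning, smoothing and the bootstrap composite

Standardised values are averaged in non-overlapping bins of 10 yr,
aligned to multiples of the bin width (bin b covers [b·w, (b+1)·w);
negative bins are allowed). The bin value is the mean, not the sum, so
unevenly sampled records do not dominate through sample density. The
wording "bootstrap … with a moving window procedure using
non-overlapping bins" admits a sliding-bin reading; this implementation
bins first (fixed, non-overlapping) and bootstraps afterwards, which is
the only reading in which "non-overlapping" has force.

The smoother is a locally weighted linear regression with tricube
weights over a fixed window [t − h, t + h] (h = 500 yr for the trend,
200 yr for the high-frequency curve). A fixed half-width — rather than
the nearest-neighbour fraction used by common lowess implementations —
is required for the bandwidth to mean the same thing at every age, and
is why the smoother is implemented here rather than taken from
statsmodels. Windows with fewer than three points yield missing values:
gaps propagate, they are not bridged. On exactly linear input the
smoother reproduces the line to machine precision (local linear fits
are exact on polynomials of degree ≤ 1), which the tests assert.

The composite resamples *sites* with replacement 999 times (the site,
not the sample, is the exchangeable unit of a regional design), pools
each draw's binned values as a per-bin mean weighted by the multiset of
drawn sites, smooths each pooled draw, and reports the across-draw mean
with a percentile confidence band. The default band is 90%, with 95%
available by configuration; published descriptions of this procedure
alternate between the two levels, and both are first-class here rather
than silently resolved. All draws flow from one `numpy.random.Generator`
passed by the caller, so composites are exactly reproducible.

## Pollen source radius and the MAT transfer function

The calibration target for genus g at surface sample s is the
unweighted mean biomass of the grid cells within radius r_g of s. The
radius is genus-specific because pollen source areas differ strongly
between taxa (heavy local pollen vs widely dispersed Pinus pollen);
r_g is chosen by sweeping a candidate list (default 1, 5, 15, 20, 30,
50, 75, 100, 120, 150 km) and maximising leave-one-out predictive
R² = 1 − SSE/SST of the MAT predictions, ties to the smaller radius.
Candidate radii finer than the biomass grid can fail for some samples;
such radii stay in the diagnostic table with R² = NaN and a warning
instead of aborting the sweep.

Dissimilarity between pollen spectra is the squared-chord distance
Σ(√p − √q)² — the palynological standard — computed on proportions, so
predictions are invariant to total count. Euclidean-on-roots and
Bray-Curtis are available as options. A prediction is the unweighted
mean biomass of the k nearest training spectra, with ties at the k-th
rank broken by training-sample order (stable sort). k is selected by
bootstrap resampling: each replicate takes a bootstrap sample as the
training set, predicts the out-of-bag samples, and pools squared errors
into RMSEP_k; empty out-of-bag replicates are redrawn. Distance-weighted
averaging is deliberately not the default: with the small k typical of
these calibrations it adds variance without measurable skill.

Fossil assemblages qualify only if they lie within 100 km of a
charcoal site; each takes the zone of its nearest charcoal site. The
conifer/broadleaf ratio is Σ(Abies, Picea, Pinus) / Σ(Acer, Betula,
Populus) with the denominator floored at δ = 0.1 t ha⁻¹ (capped steps
are flagged) so near-pure conifer landscapes give a large finite ratio
rather than infinity; steps with both sums zero are missing.

## Driver series

Seasonal values are the cellwise means of the three monthly rasters
(MAM, JJA). Anomalies are differences for temperature and
100·(x − x₀)/x₀ for precipitation, with zero-baseline cells set to
missing (a percent change is undefined there). Downscaling assigns each
fine baseline cell the anomaly of the coarse cell covering it (nearest
centre within half the coarse spacing; uncovered cells are missing),
additively for temperature and multiplicatively for precipitation.
Climate is kept at its native millennial resolution — no temporal
interpolation — and the two GCM variants are analysed separately
throughout; they are never averaged before correlation.

## Attribution

Biomass burning, vegetation and population series are averaged into
millennial steps ([m, m+1000)), stacked over 4 regions × 8 millennia
into a 32-row panel, and centred to zero mean within region (variance
is deliberately not rescaled; the centering removes between-region
level differences, and it is applied to the response as well as the
predictors). The semipartial Spearman correlation of burning y with
driver x given the remaining drivers Z rank-transforms all columns
(average ranks on ties), residualises rank(x) on rank(Z) by least
squares, and correlates rank(y) with the residuals — variation is
removed from the driver only, never from the response, so the sr² of
different drivers partition comparably.

Significance is the two-sided t-test of the unique contribution of x
in the rank regression of y on (x, Z):
t = sr·√(n − 2 − g)/√(1 − R²_full), df = n − 2 − g. The frequently
quoted variant that replaces R²_full by sr² was evaluated and found
conservative at this design size (empirical type-I ≈ 0.031 at n = 32,
g = 6, vs ≈ 0.05 for the form used); with no covariates both reduce to
the ordinary Spearman t-test. Raw p-values are reported (no
multiple-testing correction, matching how such tables are customarily
presented); a Holm step-down adjustment is available but off by
default. The functional form of significant relationships is explored
with one-component PLS regression on the centred panel (predictors and
response centred, not scaled); with a single predictor this reduces
exactly to OLS, which doubles as its oracle test.

## Synthetic data: what it emulates, and what it does not

The generators produce inputs with the statistical structure the
pipeline assumes and a known ground truth for recovery tests; all
randomness flows through `numpy.random.default_rng([seed, stream])`
with a fixed stream per generator (PCG64), so a fixed seed is
bit-reproducible and generators can be called independently while
sharing the same latent drivers.

* **Drivers**: per-zone millennial series are smoothed Gaussian random
  walks, standardised within zone; population density grows
  monotonically toward the present (log growth 3 over the span,
  strongest in the temperate zone). Climate "models" are two noisy
  copies (sd 0.1) of one latent field plus spatial noise (sd 0.2) —
  enough to exercise the dual-model design, with zero inter-model noise
  degenerating to identical extractions.
* **Charcoal**: each zone has a latent burning index b(t) — Gaussian-
  filtered noise with 800-yr correlation length and unit amplitude —
  plus a linear driver response on the log-intensity scale. Site
  concentrations are gamma-Poisson (dispersion 0.5, hence variance far
  above the mean and a positive zero fraction) around
  20·s_site·exp(b(t)) with a lognormal site scale (sd 1), so the
  standardisation chain is genuinely needed and the Box-Cox fit has a
  non-trivial optimum. Sediment histories are gamma-jittered, rescaled
  to span the study period. The default injected effect is summer
  precipitation at −1.0 per driver SD: strong enough that a 32-row
  panel detects it with ~95% power, which is the generator's purpose —
  an embedded effect that the pipeline must find; effects at the
  margin of detectability can be configured but make recovery a coin
  flip by construction.
* **Modern calibration**: per-genus biomass surfaces are lognormal
  transforms of Gaussian-filtered fields with 12-km correlation length
  on a 0.05° grid — patchy enough that averaging radii of 5, 10, 20,
  40 and 80 km are statistically distinguishable, which is what makes
  the true source radius (the recoverable ground truth) identifiable.
  Pollen counts are multinomial (n = 300) with expected proportions
  proportional to source-area biomass under lognormal noise (sd 0.15);
  the "other" taxon takes a fixed weight.
* **Fossil pollen**: counts follow prescribed per-genus biomass
  trajectories through the same pollen-production link; the boreal
  mixedwood zone carries a conifer rise (and broadleaf fall) at
  4000 BP, the recovery target for the ratio series.
* **Time span**: the default synthetic span is 0–8000 BP so that the
  millennium bin [7000, 8000) is populated and the panel has its full
  8 millennia per region; millennium labels run 0–7000 BP.

The generators emulate *statistical* structure only: no mechanistic
fire, vegetation or dispersal model, no spatially realistic GCM
fields, no taphonomy. Passing recovery tests therefore demonstrates
that the pipeline recovers effects of the assumed form at realistic
noise levels — not that those forms exhaust real sedimentary data.

## Problem sizes used in tests and the reproduction script

The composite recovery experiments run 15 sites per zone with the full
999 bootstrap draws; effect recovery uses 100 independent 32-row
panels; radius recovery 50 independent calibrations of 60 surface
samples; the null calibration of the semipartial test 1000 replicates.
Unit tests use smaller configurations (4–8 sites, 29–199 draws) chosen
so each one still exercises the property it asserts.

## Known limitations

* Age-depth interpolation is linear only; records whose original
  age models were spline- or Bacon-based are approximated.
* The MAT does not model pollen dispersal mechanistically; the source
  radius is an empirical skill optimum, not a physical quantity.
* Semipartial correlation measures unique *association* at millennial
  scale; with 8 time steps per region, strongly autocorrelated drivers
  can still produce spurious associations, and no lag structure is
  considered.
* The panel treats region × millennium cells as exchangeable after
  centering; residual temporal autocorrelation within regions is not
  modelled.
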