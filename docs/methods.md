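# Methods

This note documents the models behind `vinecast`, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Solar geometry

Declination uses the Spencer (1971) trigonometric series in the day-angle
Γ = 2π(DOY−1)/365; it agrees with ephemeris-grade calculators (the NOAA
Julian-century formulation, kept as an independent oracle in the test
suite) to a few hundredths of a degree. Elevation and azimuth follow from
the standard spherical-triangle relations with the hour angle
H = 15°·(t − 12) in **local solar time**; conversion from civil time and
longitude is an I/O concern and deliberately kept out of the geometry.

Day length is the interval the sun centre spends above a configurable
altitude threshold, default −0.833° (≈0.567° atmospheric refraction plus
half the 0.533° solar disc). The threshold matters: only with it does a
midsummer day at 45.1°N come out at 15 h 38 min; the geometric (0°)
threshold gives ~8 minutes less. One consequence worth knowing: with a
nonzero threshold the day lengths at ±latitude do *not* sum to 24 h —
both hemispheres gain refracted daylight, up to ~44 min combined at ±60°
at the solstice — so the hemispheric-complement identity is only exact at
a 0° threshold, which is how the property test states it.

Clear-sky irradiance is a deliberately simple stand-in (the studies this
package models *measured* incident light): beam transmittance
`clearness^m` with the Kasten–Young (1989) air mass, pressure-scaled by
altitude (scale height 8435 m), and diffuse taken as 30 % of the beam
depletion projected on the horizontal. `clearness` defaults to 0.75
(clean clear sky). Irradiance is expressed as photon flux; the single
energy↔photon constant is 2.3 µmol J⁻¹ of broadband shortwave (≈4.6
µmol J⁻¹ for PAR × PAR ≈ half of global shortwave).

## Row-shadow interception (TCLI)

The canopy is an opaque rectangular slab, infinitely long along the row —
the trained-wall geometry of vertically shoot-positioned vineyards, where
calibration against scanner-bar measurements has shown the shaded-area
proxy to be accurate (R² ≈ 0.96). On flat ground:

    width = canopy_width + canopy_height · cot(elevation) · |sin(sun_az − row_az)|
    TCLI% = 100 · min(width / row_spacing, 1)

The clamp represents adjacent-row shadows merging across the alley; the
canopy base height shifts the band sideways without widening it, so it
does not enter the fraction. Porosity is ignored (opaque slab), and only
the direct beam defines the shadow — diffuse interception is not
modelled. Slopes are handled by rotating the sun vector into a
ground-aligned frame (Rodrigues rotation about the horizontal axis
perpendicular to the aspect direction) before projection; flat ground is
the calibrated default, and sloped behaviour is covered by bounds/property
tests only.

Within the sunrise–sunset profile, instants with the sun in the
refraction band (elevation ≤ 0) count as 100 % interception, matching the
observed dawn/dusk plateaus. For a 35° NE–SW row at 45.1°N in midsummer
the profile is U-shaped: 100 % at the extremes and a minimum of ~15–20 %
in the early afternoon (~13:00 solar), because the minimum trades off
maximum elevation (noon) against sun–row alignment (later).

## Canopy transpiration

Whole-canopy transpiration T_c (mmol H₂O s⁻¹) is an intercept-free
quadratic with exactly six terms — the three squares and three cross
products of x₁ = direct light (µmol m⁻² s⁻¹), x₂ = air VPD (**hPa**),
x₃ = TCLI (%):

    T_c = a·x₁² + b·x₂² + c·x₃² + d·x₁x₂ + e·x₁x₃ + f·x₂x₃

No linear terms and no intercept, so T_c(0,0,0) = 0 identically. The hPa
convention for VPD is load-bearing: with the shipped 20 June coefficients
and hPa inputs, realistic midsummer drivers (1500 µmol m⁻² s⁻¹, 2.5 kPa,
30 % TCLI) yield ≈6.2 mmol s⁻¹ ≈ 400 g h⁻¹ — the observed afternoon
peak — whereas kPa inputs would be off by two orders of magnitude.
Kilopascal inputs must be converted at the boundary (×10).

Fitting is ordinary least squares on the six-column design
(`numpy.linalg.lstsq`), with explicit rank and sample-size checks
(`UnderdeterminedFitError`). R² is reported against the centred total sum
of squares. `compare_tc_models` sweeps both forms (linear with intercept,
quadratic intercept-free) over every non-empty subset of the three
drivers and flags the max-R² candidate. Negative raw predictions —
possible outside the calibration domain since the form is not
sign-constrained — are clamped to zero with a logged warning.

Three published day-specific calibrations ship as named fixtures. The
1 August equation as printed ends with two x₁·x₂ terms; both the verbatim
variant (final coefficient folded onto x₁·x₂) and a corrected variant
(final term read as x₂·x₃, the canonical sixth term) are stored, and
tests exercise both. The printed August worked numbers also carry a small
internal rounding inconsistency (224 g h⁻¹ × 14 h 43 min = 3.30 L, not
the printed 3.27 L); the unit-chain code is exact arithmetic and the
tests document the discrepancy rather than hiding it.

Unit conversions are centralised: 1 mmol s⁻¹ = 18.015 × 3.6 = 64.854
g h⁻¹; litres/vine = g h⁻¹ × day-length/1000; mm/day spreads the per-vine
volume over the ground share (density/ha ÷ 10 000 m²); L m⁻² divides by
the per-vine leaf area (defaults 4000 vines ha⁻¹, 3.37 m²). Sub-daily
series integrate by the trapezoid over daylight.

## Soil water balance and warnings

Field capacity (33 kPa) and wilting point (1500 kPa) come from the Saxton
& Rawls (2006) pedotransfer regressions on sand, clay and organic-matter
percentages, including the published second-stage corrections. Plant
available water = (θ_fc − θ_wp) × depth; default rooted depth 1 m,
user-adjustable (deep-rooted mature vineyards are the known failure mode
of the 1 m default).

The daily bucket update is
`reservoir ← clamp(reservoir + P − ETs − T_c, 0, capacity)`; excess above
capacity leaves immediately as deep percolation (no runoff routing), and
demand beyond the stored water truncates as recorded unmet demand rather
than driving the store negative. Mass is conserved to machine precision
and asserted to ≤1e-9 mm over multi-year runs.

Floor evapotranspiration follows a piecewise-linear anchor schedule per
cover class, area-weighted over management zones: a 0.3 mm/day winter
baseline everywhere; in-season plateaus of 1.6 (tilled), 2.7 (winter
cover crop pre-termination), 2.5 (spontaneous grass) and 1.4 (herbicide
strip) mm/day, with linear shoulders DOY 91–120 and 280–304; and after
spring rolling a decay anchored at 2.7 (day 0) → 2.0 (+1 d) → 0.5
(+14 d) → 0.3 (+30 d). The tilled/cover-crop/rolled anchors are measured
values; the grass and herbicide plateaus are set relative to them; the
interpolant between anchors is a modelling choice, as is reading the
"+14 d" anchor as an absolute rate of 0.5 mm/day. Zones are weighted by
ground-area share alone, without canopy-shading correction.

Warnings map the remaining SAW percentage to a stoplight: green > 60 %,
yellow (40, 60], red ≤ 40 %. Both boundary points belong to the more
severe class — the conservative choice for an alert system. The season
starts at a configurable fill fraction (default: full profile,
reflecting winter recharge at budburst), and warnings are logged as an
append-only transition log rather than a per-day dump.

## Phenology harness

Each day inside a stage window — budburst DOY 65–100, flowering 140–175,
veraison 190–230 — is a binary outcome, 1 only on the observed event day
of its site-year. Daily features are as-of-date states: cumulative GDD
(base 10 °C from 1 January), cumulative radiation, cumulative FAO-56
reference ET, plus same-day Tmax, Tmean, soil temperature (fallback: a
5-day lagged rolling mean of Tmean), VPD (Tetens), RH, wind and
precipitation.

Feature screening is a Pearson correlation of per-site-year feature
states against the event DOY, retaining |r| > 0.3. The states are taken
at the *window-start* date, not the event date: the event date is unknown
at prediction time, and for thermally driven events the GDD state at a
fixed calendar date is the informative quantity (at the event date itself
the GDD sum is nearly constant by definition and the correlation
collapses).

The classifier is pluggable — gradient-boosted trees (XGBoost) by
default, with random-forest, support-vector and k-nearest-neighbour
baselines — because the contribution here is the harness, not the
learner. Splitting is 80:20, either row-wise or holding out whole
site-years (the mode the end-to-end tests use, preventing any within-
season leakage); LOOCV is available for the training phase. Resampling
(seeded over/under-sampling toward a configurable class ratio) is applied
*after* the split and only to the training partition. Date extraction
averages all in-window days whose positive-class probability exceeds a
reliability threshold (default 0.5, configurable, with a sweep utility)
and rounds to the nearest whole day; no qualifying day means an explicit
no-prediction, which RMSE-in-days scoring excludes and counts.

Metrics come verbatim from the confusion matrix: precision TP/(TP+FP),
recall TP/(TP+FN), accuracy (TP+TN)/n, F1 = TP/(TP + (FP+FN)/2), plus
threshold-free ROC-AUC (tested against a brute-force concordant-pair
oracle with ties at ½).

## Synthetic data

The generator supplies the statistical structure the pipeline assumes,
with known truth: daily mean temperature = annual sinusoid (defaults:
mean 13 °C, amplitude 10.5 °C, peak DOY 205 — a northern-Italian
mid-latitude climate) + AR(1) noise (sd 1.5 °C, ρ 0.7); fixed 9 °C
diurnal range; precipitation as a Bernoulli(0.25)–gamma(0.8, 6 mm) chain;
radiation as the site's quadrature clear-sky total scaled by a beta-
distributed daily clearness index (wet days halved); humidity around 68 %
with wet-day enrichment and a warm-anomaly drydown. The 30-min sub-daily
grid uses a zero-mean cosine wave (trough 02:00, peak 14:00) around the
daily mean, so daily and sub-daily resolutions agree exactly by
construction.

Phenology truth is a pure GDD-threshold crossing (budburst 15, flowering
380, veraison 1100 °C·day from 1 January — values in the ranges observed
for these stages in temperate vineyards) plus rounded N(0, 2 days)
jitter. Transpiration truth is the published 20 June quadratic plus
Gaussian noise at 5 % of the signal peak. Vineyard draws sample the
envelopes of real trained vineyards (spacing 2.0–3.4 m, canopy 0.9–1.4 ×
0.30–0.50 m, altitude 27–430 m, the four common row orientations). All
draws descend from a single root seed through `numpy.random.SeedSequence`
and are bit-reproducible.

What passing tests show — and what they do not: the harness recovers
GDD-driven events it generated (RMSE ≤ 3 days for the flowering-like
stage over 40 site-years at the fixed test seed), which validates the
machinery, not field skill. Real phenology has varietal, dormancy and
photoperiod structure the generator deliberately lacks; real budburst in
particular is known to occur across a very wide GDD range, and the
study-scale skill figures require the original per-vineyard weather
records, which are not deposited. The synthetic end-to-end check is a
correctness argument for the pipeline, not a forecast benchmark.

## Problem sizes and numerics

Default problem sizes: 30-min diurnal grids; 365-day seasons; 40
site-years for the end-to-end harness; n = 500 and 5 % noise for
coefficient-recovery checks; 10 seasons for conservation checks. Ties and
degenerate inputs are resolved explicitly: sun at zenith → azimuth
reported as 180°; elevation ≤ 0 → no shadow defined, full interception in
profiles; rank-deficient regression designs → error, not silent
pseudo-inverse; zero-variance features → dropped with a warning;
single-class label vectors → AUC reported as missing; weather gaps →
listed and fatal for season runs, reported and non-fatal for plain
reads. Boundary SAW values (exactly 60 % or 40 %) classify to the more
severe warning; analytic crossing-day tests therefore place the
cumulative deficit strictly past the boundary rather than on a
floating-point tie.
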