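# Methods

`rotaclim` is a desk-scale re-creation of a common climate-impact study
design for the rice–wheat double-cropping system of the humid southern
Huang-Huai-Hai plain: station daily weather and a multi-model monthly GCM
ensemble are bridged by statistical downscaling, a process-based crop model
simulates both crops of the rotation for a baseline window (1981–2010 era)
and a future window (2041–2070 era, four SSP scenarios), and the ensemble
of future-minus-baseline changes is summarized and attributed to climate
drivers by multiple regression.  Every input is synthetic and generated by
the package itself, so the full chain is reproducible and testable offline.
This note records the models, their assumptions, the defaults, and what the
synthetic setting does and does not establish.

## Station weather and radiation

Daily records carry tmax, tmin (°C), precipitation (mm) and global solar
radiation (MJ m⁻² d⁻¹); when only sunshine hours are available, radiation
follows the Angström–Prescott law `Rad = (a + b·n/N)·Ra` with
extraterrestrial radiation `Ra` and astronomical day length `N` from the
standard FAO-56 declination/sunset-hour-angle geometry.  Coefficients
(a, b) are calibrated by ordinary least squares of the transmissivity
`Rad/Ra` on the sunshine fraction `n/N`; the fit criterion is not uniquely
determined by the study design, and OLS on the transmissivity ratio is the
conventional choice.  `Tmean = (tmax + tmin)/2` throughout (standard
agro-meteorological convention).  Dates use the proleptic Gregorian
calendar with real leap years; growth windows may span the year boundary
and seasons are labelled by harvest year (wheat window Oct 15 – May 31,
rice window Jun 15 – Oct 5 by default).

## Stochastic weather generator

Occurrence of precipitation is a first-order two-state Markov chain per
calendar month (p01 = wet after dry, p11 = wet after wet); wet-day amounts
are gamma distributed (method-of-moments fit) with a 0.1 mm trace floor;
dry days are exactly zero.  tmax, tmin and radiation are generated as
monthly means conditional on the day's wet/dry state plus lag-1
autoregressive residuals with a fixed cross-correlation matrix
(tmax–tmin 0.7, tmax–rad 0.4, tmin–rad 0.1 in the shipped defaults; fitted
matrices are used when parameters come from data).  Radiation is clipped to
[0.05, 0.8·Ra] and tmin capped at tmax − 0.1 °C.  A month whose fitting
sample contains fewer than two wet days gets undefined gamma parameters and
generates dry days only; a record with no dry (or no wet) predecessors
records p01 = 1 (p11 = 0).

The shipped per-station climatologies (four stations: Hefei-, Shouxian-,
Kunshan- and Xuzhou-like) are sinusoidal monthly cycles and a monsoon
precipitation profile tuned once so that 30-year generated baselines land
inside the observed growth-window envelopes for this region (wheat window:
Tmax 13.9–14.8 °C, Tmin 4.3–6.7 °C, precipitation 220–472.9 mm, radiation
10.2–11.1 MJ m⁻²; rice window: 28.2–28.7 °C, 19.4–21.1 °C, 567.2–654.6 mm,
14–14.9 MJ m⁻²).

What the generator emulates: seasonal cycles, wet-spell persistence,
skewed daily rainfall, wet-day cooling/dimming, day-to-day temperature
autocorrelation.  What it does not: multi-day synoptic organization beyond
lag-1, interannual modes (ENSO-like variability), trends within a window,
spatial coherence between stations, or extreme-event tails beyond the
gamma.  Tests passing on this generator validate the pipeline's wiring on
realistic marginal statistics; they are not evidence about real-station
extremes.

## Pseudo-GCM ensemble

Each scenario is specified by a mean warming with inter-model spread, a
radiation delta (negative under the high-aerosol SSP370-like pathway), and
a multiplicative precipitation factor; each pseudo-model additionally draws
static biases (additive for temperatures and radiation, multiplicative for
precipitation) so the baseline-window model distributions genuinely differ
from the pseudo-observations — the precondition that makes bias correction
non-trivial.  Defaults: warming 1.5/2.0/2.6/3.2 °C (spread 0.5–0.8 °C),
radiation +0.6/+0.4/−0.5/+0.5 MJ m⁻², precipitation factor 1.05–1.08
(spread 0.05–0.08), bias sd 0.8 °C / 0.5 MJ m⁻² / 12% precipitation.

Monthly values sit on a 5×5 grid at 1° spacing around each station with a
smooth latitudinal gradient (−0.55 °C per degree northward); real GCM
resolutions and spatial fields are not imitated.  Interannual monthly
variability is calibrated against a 30-year daily sample generated from the
same climatology, so pseudo-GCM monthly distributions match the station's
up to bias and delta — this keeps the quantile correction near unit slope
and lets imposed deltas survive the downscaling chain within tolerance.
The future window reuses the baseline window's anomaly draws (common random
numbers): a zero-delta scenario reproduces its baseline exactly, making the
null experiment exactly zero and pairing the ensemble statistics.

## Downscaling

Spatial step: inverse-distance-weighted interpolation (power 2, 4 nearest
nodes, great-circle distances; a node coinciding with the station is
returned exactly; equidistant ties share weight equally) produces station
monthly series, then empirical quantile–quantile mapping per variable and
calendar month (30 knots, or the sample size if smaller) corrects the
model's baseline-window distribution to the observed one.  The fitted maps
are applied to both windows; outside the fitted range the correction
extrapolates with the constant offset of the outermost knot pair, which
preserves imposed deltas for out-of-sample future values.  Correction acts
on monthly values because that is the resolution of the GCM side.

Temporal step: the weather generator fitted to the station observations is
sampled month by month and adjusted to the corrected monthly targets:
wet-day amounts are rescaled multiplicatively to the target total (exact to
1e-9 mm; a wet target month with no generated wet day gets one uniformly
placed wet day carrying the full total), temperatures are shifted
additively, radiation is rescaled multiplicatively with the floored deficit
redistributed so the monthly mean is exact, and tmin is re-capped at
tmax − 0.1 °C (which can move the tmin monthly mean by up to ~0.05 °C —
the one deliberate deviation from exact conditioning).  Both windows of a
model use the same generator substream, so identical targets give
byte-identical daily series.

## CO₂ scenarios

Yearly concentrations for 1981–2070 are evaluated from per-scenario sums of
simple algebraic terms held in an editable YAML config.  The shipped
defaults transcribe the published fitted curves' shifted-polynomial and
linear terms; the leading non-polynomial terms of those curves are
typographically ambiguous in the source and are reconstructed as one
constant per scenario, calibrated so that every curve passes through
340 ppm in 1981 (the observed global mean for that year).  For the
highest-forcing scenario the printed linear term would force the curve
below the medium-high pathway mid-century, so its ambiguous part is the
constant alone.  The defaults are therefore a documented reconstruction,
not a transcription, and the contract is the validation suite: all values
inside a 300–1200 ppm envelope, the four curves within 10 ppm of each
other in the early 1980s with monotonically diverging spread after 2015,
2041–2070 means ordered SSP126 < SSP245 < SSP370 < SSP585, and the
SSP585-like curve monotone nondecreasing (resulting 2041–2070 means:
≈455/505/558/667 ppm).

## Crop model

A deliberately compact process model wired for the mechanisms that drive
the attribution signs; it does not reproduce any full cropping-systems
model, and all quantitative claims are about this stand-in.

Phenology.  Daily thermal time has a triangular response on Tmean: zero at
Tbase, peak (Topt − Tbase) at Topt, zero at Tupper (wheat 0/26/34 °C, rice
8/30/42 °C).  Wheat development between emergence and flowering is scaled
by a vernalization factor (linear accrual of vernal days inside a −1.3 to
15.7 °C band toward a 30-day requirement — the wide band keeps warming
monotonically accelerating rather than vernalization-limiting) and a
photoperiod factor (1 − 0.08·(14 h − day length), clamped to [0, 1]).
Thermal-time targets (wheat 120/950/645 °C d for sowing→emergence→
flowering→maturity; rice 60/1050/520 °C d after mid-June transplanting)
put wheat flowering in late April and maturity at the end of May, and rice
flowering in mid-August and maturity in late September, for the shipped
climatologies.  A season that fails to mature before its calendar cutoff
(wheat Jun 10, rice Oct 14) is flagged failed and excluded from statistics.

Growth.  Above-ground biomass accumulates as RUE · Rad · interception ·
f(CO₂) · f(water), with interception `cover_max·(1 − exp(−k·LAI))`, LAI
ramping with vegetative thermal time and senescing over the last 40% of
grain fill.  RUE defaults: wheat 1.25, rice 1.15 g MJ⁻¹.  The CO₂
fertilization factor is linear in ppm, equal to 1 at 350 ppm with slope
7×10⁻⁴ ppm⁻¹ for both C3 crops (capped at 1.5) — a mid-range C3 response
(≈ +25% per doubling).

Water.  Transpiration demand is the biomass increment times a
vapour-pressure-deficit proxy (0.75 of the tmax–tmin saturation-pressure
difference; no humidity data exists in this pipeline) divided by the
transpiration-efficiency coefficient (wheat 0.006, rice 0.008 kPa,
normalized at 350 ppm) times a CO₂ TE factor with slope 1.1×10⁻³ ppm⁻¹ —
the stomatal-conductance proxy; because the TE slope exceeds the RUE
slope, elevated CO₂ strictly lowers water use per unit yield.  A single
soil bucket (150 mm plant-available capacity) supplies transpiration up to
0.12·storage per day, evaporates from the uncovered fraction at 0.9 of
Priestley–Taylor potential ET (α = 1.26, net radiation 0.75 of global,
crop coefficients wheat 1.0, rice 1.15), sheds rain above 50 mm d⁻¹ as
runoff, and drains 70% of any above-capacity excess (the rest runs off).
The balance closes to machine precision each day by construction and is
audited per season (< 1e-6 mm).  Rice is irrigated by daily refill to
capacity (ponded-field proxy), which keeps its supply factor at 1; wheat
is rain-fed.  Reported ET is transpiration plus soil evaporation,
including the irrigation-fed evaporation of the rice paddy proxy.

Yield.  A harvest index accrues during the reproductive period (wheat
0.011 d⁻¹ capped at 0.48; rice 0.013/0.50) and each day's accrual is
reduced by `penalty · max(0, tmax − threshold)` (thresholds 30 °C wheat,
35 °C rice; penalty 4×10⁻³ per °C d) — the grain-set heat-stress channel.
Yield = HI · biomass at maturity; WUE = yield/ET.  Typical baseline output
under the shipped climatologies: wheat ≈ 7.4 t ha⁻¹, rice ≈ 4.7 t ha⁻¹,
annual rotation ET ≈ 700 mm.  Nitrogen is assumed non-limiting; pests,
lodging and extreme-event damage functions are out of scope.

## Ensemble experiment and attribution

For every station × scenario × pseudo-model the rotation is simulated over
both windows; per-crop means over non-failed seasons give FD/MD/RGP, yield,
ET and WUE, and "total" rows sum the two crops (total WUE = total yield /
total ET).  Climate deltas use each crop's growth window (annual values for
total rows); the CO₂ delta is the difference of annual means over the two
windows.  Cells with more than 20% failed seasons are flagged and excluded
from regressions.  Box statistics (mean, median, 10/25/75/90th percentiles
with the linear-interpolation convention) summarize the model dimension.

The attribution regressions mirror the standard Δ-form
`ΔY = a·ΔTmean + b·ΔRad + c·ΔPre + d·Δ[CO2]` for ΔYield, ΔET and ΔWUE per
crop, pooled over stations × scenarios × models, fitted without intercept
(the Δ-form passes through the origin by construction); R² is the
uncentered coefficient of determination appropriate for a no-intercept
model, and an intercept variant is available behind a flag for sensitivity.
Significance stars mark p < 0.05 / p < 0.01 from two-sided t-tests without
multiple-testing correction.  The sign report scores significant
coefficients against the expected mechanism pattern — yield (−Tmean, +Rad,
+Pre, +CO₂), ET (+Rad, −CO₂), WUE (−Tmean, +CO₂) — as match / mismatch /
not-significant.  On the default configuration the pooled-total cells are
significant matches and no cell is a significant mismatch; weakly
identified per-crop cells (notably rice yield vs precipitation — the rice
crop is irrigated — and rice yield vs CO₂) may stay not-significant at this
ensemble size.  This validates the stand-in model's mechanism wiring, not
any full crop model.

## Problem sizes and numerical choices

The default experiment uses 4 stations × 8 pseudo-models × 4 scenarios
with 10-year windows (384 ensemble rows, 128 regression points per crop),
which the package treats as its standard configuration; ensemble size,
window length and grid layout are configurable.  Master seeds expand into
labelled substreams (station/model/scenario), so every artifact is
reproducible from one integer.  Degenerate inputs are handled explicitly:
polar night returns the overcast radiation term, all-dry months generate
dry days, empty IDW node lists and rank-deficient regression designs raise
errors naming the offending input, and implausible CO₂ configurations fail
validation naming the offending year.

## Known limitations

Single-station independence (no spatial weather coherence); monthly-only
GCM emulation with stationary deltas per window; a one-bucket soil with no
nitrogen, pest or extreme-event processes; VPD proxied from the diurnal
temperature range; CO₂ responses linearized around 350 ppm; no sowing-date
or cultivar adaptation.  Quantities that depend on real GCM fields or on a
calibrated cropping-systems model (absolute changes at real stations,
published regression coefficients) are outside what this pipeline can or
tries to reproduce.
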