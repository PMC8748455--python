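# Methods

This note documents the models, parameter choices and numerical
conventions behind `lakemox`, and what the synthetic test bed does and
does not establish about real lake data.

## Rate definitions

Methanotrophic carbon consumption (MCC, µg C L⁻¹ d⁻¹) is defined through
the first-order decay of CH4 in dark, unamended incubations. The rate
constant `k` (d⁻¹) is the absolute OLS slope of ln[CH4] against time;
replicate flasks are pooled into a single regression by default (more
points per fit; per-flask fits are available via `pooled=False`). The
oxidation rate attributed to a time point is `k · [CH4]`, and since CH4 is
the sole carbon source of obligate methanotrophs, MCC is that rate times
12.011 µg C per µmol. A fit's quality flag compares its r² to a
configurable threshold (default 0.92, the level at which decay curves are
effectively log-linear); QC flags propagate into rate tables rather than
silently dropping fits.

Heterotrophic carbon consumption is `HCC = HBP + HBR`, exactly. HBP
converts leucine incorporation (pmol L⁻¹ h⁻¹) with two explicit factors:
`leucine_to_carbon` (default 1.55 kg C mol⁻¹) and `isotope_dilution`
(default 2). These defaults are this package's, chosen from the common
range used with the standard leucine protocol, and should be set to the
values of the local protocol; they are deliberately not buried constants.
HBR is the absolute O2 drawdown slope (mg L⁻¹ h⁻¹ over ≥ 48 h, flagged
otherwise) converted at a respiratory quotient of 1 (configurable):
mg O2 → µmol O2 → µmol C → µg C, per day. Because HBR incubations are
pre-filtered (1.2 µm), the filtered rate is multiplied by the
unfiltered/filtered ratio of non-MOB DAPI biomass; factors below 1 are
honoured with a warning (filtration should not add biomass). No
temperature correction is applied to HBP measured at room temperature —
the resulting bias makes the methanotrophy share conservative.

## Census conversions

Counts and per-cell projected areas by group (DAPI = total prokaryotes,
including archaea, hence never labelled "bacterial"; CARD-FISH Alpha- and
Gamma-MOB) pass a minimum-area screen of 22 pixels at 0.01 µm²/px
(= 0.22 µm²), removing viruses and eukaryotic nuclei. Volumes assume
spherical cells: equivalent-circle diameter `d = 2√(A/π)`, volume
`(π/6)d³`. Biomass uses 63 fg C µm⁻³. Abundance scale-up is mean count
per field × (effective filter area / field area) / filtered volume; the
microscope's area ratio is an explicit input, not a constant. The
biomass-vs-count enrichment of a small group equals its mean-volume ratio
to the community in the small-fraction limit (tested at fractions 10⁻³
and 10⁻⁴). Specific activity is rate over consumer biomass (MOB biomass
for MCC, non-MOB DAPI biomass for HCC); growth rate is specific activity
times a 0.30 growth efficiency. Cell circularity is not computed: the
census input schema carries areas only.

## Kinetics model

The water-column MOX rate is

    ln MOX = a + b·ln[CH4] + c/T + ln(e^(−p·[O2]) − e^(−(p+q)·[O2]))

with defaults a = 20.08, b = 0.79, c = −5669.61 K, p = 0.01 µM⁻¹,
q = 0.18 µM⁻¹; CH4/O2 in µM, T in Kelvin, MOX in µmol L⁻¹ d⁻¹ (the
intercept implicitly carries the rate units). The O2 bracket is exactly
zero in anoxia and peaks at ln((p+q)/p)/q ≈ 16.36 µM. Temperature is
Kelvin at the interface; °C-to-K conversion happens at a single call site
in `column_mox`. Inputs outside the roughly calibrated 271–313 K band
warn rather than fail.

Sensor O2 is first offset-calibrated (`−6.392 + 1.0228 · measured`, µM
scale; the calibration is applied on µM, an ordering the configuration
exposes), floored at zero, and flagged anoxic below 0.2 mg L⁻¹ (6.25 µM)
— the sensor's detection limit, treated as the operational anoxia rule.
Anoxic depths get zero aerobic MOX; flooring negative calibrated values
to zero keeps the methanotrophy estimate conservative.

`fit_params` refits all five coefficients from (CH4, O2, T, ln rate)
observations by separable least squares: the model is linear in (a, b, c)
given (p, q), so an outer Levenberg–Marquardt search over log(p, q)
profiles the linear part out by OLS. On noise-free self-generated data the
coefficients return to ~10⁻⁹ relative; degenerate designs (a predictor
with no spread) raise an identifiability error naming the predictor.

## Stratification and upscaling

Layers are detected from the density profile, with density from the
Martin & McCutcheon (1999) freshwater polynomial (maximum near 4 °C).
A profile whose temperature range is under 1 °C is unstratified. Otherwise
density slopes are evaluated between successive depths at segment
midpoints; the maximum-slope segment anchors the metalimnion and the
bounds are found by walking outward to the first segment below the
0.1 kg m⁻³ m⁻¹ threshold, linearly interpolating the crossing — the same
contract as rLakeAnalyzer's `meta.depths`. Two conventions are ours: a
profile whose maximum slope never reaches the threshold is unstratified,
and the interpolated crossing is clamped to the grid extent of the steep
region, so boundaries cannot land inside an adjacent well-mixed segment on
near-step profiles (this differs from plain midpoint interpolation by at
most half a grid step, and only on near-discontinuous profiles).
A boundary depth belongs to the upper layer.

Slab volumes between grid depths are trapezoids of the hypsographic
areas (linear interpolation; grids deeper than the tabulated curve raise
an extrapolation error). Each grid depth carries half of each adjacent
slab, making the volume-weighted rate sum the trapezoid rule in depth:
totals are invariant to refining a piecewise-linear profile to well
within 2%, and the per-depth volumes still sum exactly to the lake
volume. Heterotrophic rates are piecewise-constant per layer (two layers
— epilimnion bottom as divider — for lakes without a persistent
metalimnion; one layer if no boundary is available). The budget reports
totals in g C d⁻¹, the methanotrophy percentage (methanotrophy +
heterotrophy shares sum to 100 exactly; the fraction is flagged undefined
if total consumption is zero), the anoxic volume fraction, and the volume
fraction with CH4:O2 > 0.6 — anoxic depths with CH4 present count as
above-threshold, since their ratio diverges. Depths with missing CH4 are
excluded from MOX with a logged warning rather than interpolated silently.

## Gas chemistry

CH4 solubility uses the Wiesenburg & Guinasso (1979) Bunsen-coefficient
fit at salinity zero, converted to mol L⁻¹ atm⁻¹ via the 22.414 L mol⁻¹
molar volume. The coefficient set is named in `GasConstants` and
swappable; it is this package's choice of a standard freshwater-applicable
parameterization. Headspace back-calculation is a two-compartment mole
balance at the equilibration temperature: aqueous CH4 by Henry's law plus
ideal-gas headspace CH4 (zero-air assumed CH4-free; non-ideality at µatm
partial pressures is negligible), divided by the water volume. All unit
conversions are exact linear inverse pairs. No salinity or pressure
corrections and no carbonate chemistry are included.

## Season statistics

Kd PAR is the absolute OLS slope of ln(PAR) on depth. The MCC/HCC
crossing ratio smooths log-MCC and log-HCC against log CH4:O2 with
lowess (span 0.75 by default — a conventional default, exposed in the
API), finds the first upward crossing on a 200-point log grid by linear
root interpolation, and attaches an uncertainty halfwidth from a
points-level bootstrap: the larger one-sided deviation of the central-95%
bootstrap interval from the point estimate, a choice that keeps coverage
honest when the crossing's sampling distribution is skewed. If the curves
never cross, the estimate is flagged undefined rather than erroring.
Season summaries use linear-interpolation quantiles and 1.5 × IQR
whiskers; the covariate regressions (mean fraction vs DOC or Kd PAR,
OLS via statsmodels) also report the covariate value where the fitted
line predicts a 50% methanotrophy share, flagged undefined at zero slope.

## Synthetic lakes

The generator emulates the statistical structure the analysis assumes:
temperature follows a normalized logistic between epilimnetic and
hypolimnetic values centered at the thermocline (isothermal when
unstratified); O2 declines monotonically along an oxycline tied to the
thermocline; CH4 rises monotonically with a normalized exponential shape
hitting the surface and bottom values exactly (so the 0.02–455 µM
envelope is exact); hypsography is `A0 (1 − z/zmax)^e` with `e = 0`
denoting an exact cylinder. Profile shapes are deterministic; randomness
enters through incubation noise (multiplicative lognormal, mean one —
concentrations stay positive and instrument error scales with signal;
default CV 0.05, user-settable, as within-replicate measurement CV is a
free parameter), census draws (Poisson field counts, binomial MOB
subsets, lognormal biovolumes truncated at the 0.22 µm² screen), and
suite-level lake characteristics. All randomness derives from one root
seed through named `numpy` SeedSequence streams; identical inputs give
byte-identical serialized outputs.

`gen_lake_suite` spans DOC ≈ 2.6–10.9 mg L⁻¹ with Kd PAR and hypolimnetic
CH4 rising with DOC, two unstratified shallow lakes out of six, 4–16
dated profiles per lake, and a season in which the thermocline deepens,
the CH4 stock grows and bottom O2 erodes toward anoxia. The end-to-end
pipeline derives incubation decay constants from the kinetics model at
layer mean conditions and heterotrophic rates from the DOC gradient
(O2 slope 0.0012 + 0.0007·DOC mg L⁻¹ h⁻¹ with depth attenuation, leucine
incorporation 12 + 3·DOC pmol L⁻¹ h⁻¹), placing HCC in the realistic
25–134 µg C L⁻¹ d⁻¹ band.

What passing tests show — and don't. The synthetic suite verifies unit
chains, estimator calibration (decay-k error, kinetics coefficient bias,
crossing recovery), volume bookkeeping and the qualitative responses
(anoxia suppresses the methanotrophy share; hypolimnetic CH4 raises it).
It does not enforce an across-lake positive fraction–DOC relationship:
lake morphometry is drawn independently of DOC, so a high-DOC lake with a
small hypolimnion can show a modest methanotrophy share, and suite-level
regressions can come out flat. Real profiles also carry microstructure,
internal waves and sensor drift that the smooth deterministic shapes do
not emulate; conclusions about field data require field profiles.

## Problem sizes

Default test and pipeline sizes are desk-scale by design: 10 × 10 × 8
factorial grids for refits, 500 seeded incubations and 200 kinetics
replications for calibration checks, 100 synthetic sets × 100 bootstrap
resamples for crossing coverage, and six-lake seasons of 4–16 profiles.
The full suite runs in about a minute on one core.
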