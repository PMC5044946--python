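# Methods

## The model

`irrisim` estimates crop irrigation demand with a single-layer soil-water
bucket run at a daily time step over the rooting zone (default 0–60 cm of a
sandy brown podzolic soil, map unit 31). Soil water content (SWC) is
bookkept in l/m³ of soil on a scale where 100 % volumetric water content is
1000 l/m³, so a volumetric percentage `x` converts to `10·x` l/m³. For the
default soil (field capacity 24 %, available water capacity 17 %, wilting
point 7 %) the bucket bounds are 240 l/m³ (field capacity, upper clamp) and
70 l/m³ (stagnant water, lower clamp).

Each day inside the irrigation season:

1. the climatic balance is added: `SWC ← SWC + k·(P − ET0)` with `P` daily
   precipitation (mm) and `ET0` reference evapotranspiration (mm);
2. the result is clamped to `[70, 240]`;
3. if the clamped value lies **strictly below** the trigger threshold —
   stagnant water plus 20 % of the AWC storage, i.e. `70 + 0.2·170 = 104`
   l/m³ (10.4 %) — a single irrigation event of 20 mm/m² is added and the
   content re-clamped to the ceiling. At most one event fires per day; if
   the content is still below the trigger afterwards, the next opportunity
   is the next day.

### Unit conventions

The default convention (`unit_convention="direct"`) adds water depths in mm
one-to-one to the l/m³ state (`k = 1`), so one 20 mm event raises the
percent-scale content by exactly 2 percentage points. This bookkeeping is
not physically consistent with a 60 cm rooting zone (20 mm spread over
0.6 m is +33.3 l/m³ of soil); the `depth_scaled` convention
(`k = 1000/(10·depth_cm)`) is provided for physically consistent runs. The
default favours fidelity to the established bookkeeping; the alternative is
one policy field away.

### Seasons, windows and rotations

Irrigation is only considered inside a per-crop window
`[start_doy, maturity_start_doy)`, half-open: no irrigation on the
maturation start day itself. Maturation is assumed to begin exactly three
weeks before harvest for every crop, year and scenario. The common season
start is day-of-year 107 with a start content of 224.9 l/m³; both ship as
defaults and can be re-derived for any climate with
`determine_window_start` (below). DOY constants are applied unchanged in
leap years.

Soil water does **not** carry over between years: every season re-starts at
(107, 224.9 l/m³). This mirrors the use of one representative start state
for all years and crops; it under-estimates demand after exceptionally dry
winters, a known limitation.

A rotation plan cycles an ordered crop list (default sugar beet → potato →
winter rye → winter barley, anchored so 1991 grows sugar beet). Annual
totals are `20 mm × events`; the regulatory check computes a trailing 7-year
moving average (current year plus six predecessors; warm-up years without a
full history are omitted, never zero-filled) and flags years whose average
**strictly exceeds** the 79 mm/m²·yr cap — the cap itself is permitted.

### Determining the season start

`determine_window_start` runs the bucket continuously with irrigation off
from full saturation on the first day of a multi-decade series, averages
the daily SWC by day-of-year, and likewise averages the climatic balance
`P − ET0` by day-of-year. The season start is the first DOY from which the
averaged balance stays negative for a configurable confirmation run
(default 14 days; the run absorbs sampling noise around the crossing), and
the start content is the DOY-averaged SWC at that day. A balance that never
stays negative yields an explicit "no irrigation season" result. DOY 366 is
excluded from the search (too few samples). An alternative criterion —
the day the averaged SWC itself begins to decline noticeably — describes
the same crossing; the balance sign is the sharper rule and is what is
implemented.

## Reference evapotranspiration

`penman_monteith_et0` implements the FAO-56 grass reference formulation

    ET0 = [0.408·Δ·(Rn − G) + γ·(900/(T+273))·u2·(es − ea)]
          / [Δ + γ·(1 + 0.34·u2)]

with Δ from the saturation vapour-pressure curve, γ = 0.665·10⁻³·P (default
P = 101.3 kPa). Negative results (negative net radiation, strong advection)
are floored at 0 mm/day because the bucket treats ET strictly as a loss.
Missing drivers raise an error rather than defaulting silently. The
implementation reproduces the standard guideline daily worked example
(ET0 = 3.9 mm/day) within 0.05 mm/day.

## The synthetic climate generator

The generator stands in for multi-decade observational and
scenario-downscaled daily series that are not publicly redistributable. It
emulates their statistical skeleton, not their weather:

* **Temperature**: seasonal cosine (baseline 8.7 °C, amplitude 8.5 °C,
  peak near DOY 200 — a north-German lowland climatology), a linear ramp
  reaching `temp_trend` °C at the period end, an interannual anomaly
  (σ = 0.4 °C) and daily noise (σ = 3 °C).
* **Precipitation**: first-order two-state Markov occurrence chain
  (P(wet|dry) = 0.32, P(wet|wet) = 0.55 → stationary wet fraction ≈ 0.42)
  with gamma wet-day amounts (shape 0.75), calibrated so the expected
  annual total equals `annual_precip_mean` (default 654.4 mm/yr, the
  reference-period mean). `precip_delta` scales amounts along a linear ramp.
  A deterministic `uniform` mode spreads the annual mean evenly over the
  year; it exists so that a zero-noise configuration is exactly periodic,
  and for analytic fixtures.
* **ET0**: by default a direct seasonal cosine with annual total 600 mm
  (winter ≈ 0.1, summer ≈ 3.2 mm/day), multiplied by a ramp reaching
  `1 + et_trend/600` and with daily noise (σ = 0.45 mm), floored at 0. A
  `drivers` mode instead generates net radiation (seasonal, cloud-reduced
  on wet days), lognormal wind, and humidity drivers and computes ET0
  through the Penman-Monteith routine, so the full pathway is exercised.

Scenario presets set `(temp_trend, et_trend, precip_delta)` to
(+0.9 °C, −8.7, +44.7), (+1.3 °C, +5.6, +45.0) and (+1.7 °C, +28.4, +14.1)
mm/yr for `Tmin`/`Tmed`/`Tmax`, reproducing the scenario contrasts (the
warmest run pairs the largest ET increase with the smallest rainfall gain);
`observation` is trend-free. Trends are ramps reaching the quoted value at
the period end.

What the generator does **not** emulate: spatial structure, temperature–
precipitation cross-correlation beyond wet-day cloudiness, seasonal
redistribution of rainfall, autocorrelated heat waves, and the observed
seasonal asymmetry of trends. Passing tests therefore demonstrate the
correctness and qualitative behaviour of the simulation machinery under a
realistic stochastic climate, not a reproduction of any particular region's
series: with this climatology the season-start search lands later than day
107 and mean annual demand (≈ 20–30 mm/yr for the default rotation) sits at
the low end of the real region's range.

## Trend statistics

`kendall_tau_b` computes Kendall's S over (year, value) pairs and
tau-b = S/√((n0−n1)(n0−n2)) with tie terms n1, n2. P-values: exact
enumeration of the null distribution via the inversion-number generating
polynomial for n ≤ 10 without ties; full permutation enumeration for tied
series up to n = 6 (beyond that, n! enumeration is disproportionate to the
approximation error); otherwise the normal approximation with tie-corrected
variance and a continuity correction of 1. An all-constant series reports
tau as undefined (None), never 0. `ols_trend` (via `scipy.stats.linregress`)
reports the slope in mm/yr per year and R²; a constant response is defined
to have slope 0 and R² = 0 for stable reporting. No seasonal Mann-Kendall
variant, Sen's slope or autocorrelation correction is offered — the series
here are annual.

The statistical test suite sizes were fixed by a-priori power analysis: a
+1 mm/yr trend over 60 years with 30 mm interannual noise gives an analytic
Mann-Kendall power near 0.99 at α = 0.05, comfortably above the ≥ 80 %
check; the null-size check uses the same design without drift.

## Numerical choices and degenerate inputs

* Trigger comparison is strict (`<`); cap comparison is strict (`>`).
* Quantile-year selection uses the linear-interpolation empirical quantile
  and breaks distance ties toward the earliest year.
* Profile consistency (wilting + AWC = field capacity) is enforced to
  1e-9; bucket-entry states are validated against the clamp bounds.
* Crops whose maturation starts on or before the season start day get a
  zero-length window flagged `irrigable=False` rather than an exception;
  a harvest day that would push maturation to DOY 1 or earlier is rejected.
* Climate CSVs are written with `%.17g` and read with correctly-rounded
  float parsing so write→read is the identity.
* Monotone dominance (pointwise wetter climate ⇒ no more irrigation) holds
  only up to the 20 mm event granularity; the property is asserted within
  one event amount.

## Problem sizes

The bundled checks run 10⁵ randomized bucket days, 100 random seasons
against an independent brute-force oracle, exhaustive tau-b verification
over all value series of length ≤ 6 on {0,1,2}, 2 × 500 Mann-Kendall
simulations (power and size), and a 3-scenario × 20-seed × 60-year
rotation comparison — sizes chosen to make the stochastic assertions
stable while keeping the default suite quick on one CPU.
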