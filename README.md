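# irrisim

Simulation of crop irrigation demand under climate scenarios with a daily
soil-water bucket model.

In sandy regions where field agriculture depends on groundwater-fed
irrigation, regulators cap annual extraction — here 79 mm/m²·yr evaluated
as a 7-year trailing moving average — and the operational question is
whether a warming climate pushes demand past that cap. `irrisim` answers it
with a deliberately transparent model chain aimed at agro-ecohydrologists
and water-resource planners:

1. **Climate**: daily series of mean temperature, precipitation and FAO-56
   Penman-Monteith reference evapotranspiration (ET0), either read from CSV
   or drawn from a seedable stochastic generator with scenario presets
   (`observation`, `Tmin`, `Tmed`, `Tmax`) that emulate low/median/high
   warming runs of a high-emission pathway.
2. **Bucket model**: soil water content `S` (l/m³, 100 % ≙ 1000 l/m³) over
   a 0–60 cm rooting zone, updated daily as

       S(n+1) = clamp( S(n) + P(n) − ET0(n), 70, 240 )

   with an irrigation event of 20 mm/m² added whenever `S` falls strictly
   below the trigger `104 = 70 + 0.2·170` l/m³ (stagnant water + 20 % of
   available water capacity, soil type 31: FC 24 %, AWC 17 %, WP 7 %).
3. **Season & rotation accounting**: per-crop irrigation windows from the
   common season start (day 107, start value 224.9 l/m³) to three weeks
   before harvest; a crop rotation (default sugar beet → potato → winter
   rye → winter barley anchored at 1991); annual totals, 7-year moving
   averages and cap-exceedance flags.
4. **Trends**: Mann-Kendall test with Kendall's tau-b (tie-corrected, exact
   small-sample p-values) and OLS slope/R² for annual demand series.

See `docs/methods.md` for the model assumptions, generator design and
numerical choices.

## Worked example

The CLI chains four subcommands; real climate CSVs (columns
`date,tmean_c,precip_mm,et0_mm`) can replace the generated one at any point.

```sh
irrisim generate --scenario Tmax --years 1985:2070 --seed 42 --out demo
irrisim simulate --climate demo/climate.csv --out demo
irrisim trends   --annual demo/annual.csv --label Tmax-rotation
irrisim report   --run demo
```

prints

```
label,tau_b,p_value,slope_mm_per_yr,r_squared,n_years
Tmax-rotation,0.06014337793435198,0.46683369164272603,0.10849568375866789,0.0038917101130611703,86

years simulated : 86 (1985-2070)
total irrigation: 2420 mm (121 events)
mean annual     : 28.1 mm
moving average  : 5.7-57.1 mm over 80 reported years
cap exceeded in : no year
```

Reading: over 86 simulated years of the warmest scenario the rotation
needed 121 irrigation events (20 mm each, 28.1 mm/yr on average); the first
moving average is reported for 1991 (six warm-up years precede it); demand
trends upward (+0.11 mm/yr, tau-b = +0.06) but with the high interannual
variance typical of these series (R² < 0.01, p = 0.47), and the 7-year
average never exceeds the 79 mm cap under this synthetic climatology.
The same computation is available as a library:

```python
import irrisim as ir

policy   = ir.IrrigationPolicy()                      # 20 % trigger, 20 mm events
storages = ir.derive_storages(ir.SOIL_TYPE_31, policy)  # fc 240, wp 70, trigger 104
clim     = ir.generate_daily_weather(ir.scenario_config("Tmax", 1985, 2070, seed=42))
annual   = ir.cap_exceedance(ir.moving_average(
               ir.annual_irrigation_series(clim, ir.DEFAULT_ROTATION, storages, policy)))
print(annual.to_frame().tail())
```

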