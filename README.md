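# thermocomfort

Thermal-comfort computation for low-cost occupational sensor networks.

Workplace heat stress — in offices behind sunlit windows, next to industrial
machinery, in semi-outdoor barns — is driven by more than air temperature.
Small networked devices measure air temperature *T_a*, relative humidity,
globe temperature *T_g*, incident longwave irradiance *LW*, light level *L*
and (semi-outdoors) wind speed *v*. This package turns such multi-channel
streams into the quantities occupational-health users act on:

* **vapor pressure** ρ_v from *T_a* and RH (Magnus formula),
* **shortwave irradiance** SW from the lux channel (SW ≈ 0.03887·L, capped
  at 600 W m⁻² above the sensor's 15 000 lx saturation),
* **five mean radiant temperature estimates** — the forced-convection black
  globe equation

  T_mrt = [(T_g + 273.15)⁴ + (1.1·10⁸ v^0.6)/(ε_g D^0.4)·(T_g − T_a)]^¼ − 273.15,

  the one-directional radiant flux S_str ≈ F·α_k·SW + ε_p·LW converted via
  T_mrt = (S_str/(ε_p σ))^¼ − 273.15 with sphere (F = 0.167) or person
  (F = 0.06) weighting, the IR brightness temperature alone, and T_a alone,
* **PET**, the physiologically equivalent temperature, from the MEMI
  three-node (core/skin/clothing) human energy balance: the air temperature
  of a reference indoor environment (T_mrt = T_a, v = 0.1 m s⁻¹,
  ρ_v = 12 hPa, 0.9 clo, 80 W activity) in which the body reaches the same
  thermal state as in the actual environment,
* **nine thermophysiological stress classes** from PET (boundaries at
  4/8/13/18/23/29/35/41 °C, "extreme cold stress" … "extreme heat stress"),

plus per-sensor linear calibration, evaluation statistics against a
co-located reference instrument (RMSE/MBE/MAE/MSE, light-binned difference
summaries, stress-frequency distributions), and a synthetic scenario
generator with exact radiant ground truth so the whole chain is testable
without field data. See `docs/methods.md` for the model details.

## Worked example

Given `small.csv` (three 5-min records of one office device; empty cells
are absent channels):

```
timestamp,device_id,ta_c,rh_pct,tg_c,lw_wm2,tirt_c,light_lx,wind_ms
2021-08-08T10:00:00Z,office-01,24.5,48.0,26.1,430.0,,1200.0,0.0
2021-08-08T10:05:00Z,office-01,24.6,47.5,26.3,431.5,,1250.0,0.7
2021-08-08T10:10:00Z,office-01,24.8,47.0,26.6,433.0,,1300.0,0.2
```

```
thermocomfort compute --input small.csv --output enriched.csv --method globe
```

produces (abridged):

```
timestamp,...,vp_hpa,sw_wm2,v_eff_ms,tmrt_globe_c,...,pet_c,stress_level
2021-08-08T10:00:00Z,...,14.722,46.644,0.100,27.529,...,26.621,slight heat stress
2021-08-08T10:05:00Z,...,14.656,48.588,0.700,31.088,...,25.350,slight heat stress
2021-08-08T10:10:00Z,...,14.676,50.531,0.200,29.012,...,26.616,slight heat stress
```

Reading the first row: 48 % RH at 24.5 °C is 14.7 hPa of vapor pressure;
1200 lx maps to ≈ 47 W m⁻² of shortwave; the stalled anemometer (0.0 m s⁻¹)
is floored to 0.1 m s⁻¹; the 26.1 °C globe reading implies a radiant field
of 27.5 °C; and the combination yields PET = 26.6 °C — warmer than the air
because of the radiant load, and classified as slight heat stress
(PET in [23, 29) °C). The same chain is available in Python:

```python
>>> from thermocomfort import pet, classify_pet
>>> p = pet(24.5, 14.7, 31.0, 0.1)   # ta [degC], vp [hPa], tmrt [degC], v [m/s]
>>> round(p, 2), classify_pet(p)
(28.46, 'slight heat stress')
```

Other commands: `thermocomfort simulate` (scenario presets → truth + device
CSVs), `thermocomfort evaluate` (device vs reference instrument → JSON
metrics), `thermocomfort summarize` (stress-frequency CSV per device,
full-day or the 08:00–18:00 UTC working-hours window).

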