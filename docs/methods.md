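# Methods

## Sensor-channel conversions

**Vapor pressure.** RH is converted to vapor pressure with the WMO Magnus
saturation curve e_s(t) = 6.112·exp(17.62 t / (243.12 + t)) hPa and
ρ_v = RH/100 · e_s(T_a). The same curve is used everywhere a saturation
pressure is needed (expired air, skin surface) so the package carries a
single humidity formulation.

**Shortwave surrogate.** The upward-facing lux channel is converted with
the calibrated linear slope SW = 0.03887·L (W m⁻² per lx). Above the
sensor's saturation point, L > 15 000 lx, SW is fixed at 600 W m⁻². The
threshold itself lies on the linear branch ("higher than" is strict), which
leaves a small jump from 583.05 to 600 W m⁻² across it; the cap is applied
per sample, before any aggregation. The conversion is kept as calibrated
rather than smoothed so that the inverse (used by the synthetic generator)
is exact on the linear branch.

**Wind floor.** Indoor sites carry no anemometer and mean indoor air speeds
are below the starting speed of a cup anemometer, so an absent wind channel
is replaced by 0.1 m s⁻¹ and measured values are floored at 0.1 m s⁻¹
(a stalled cup reading 0.0 becomes 0.1). All downstream physics receives
the floored value `v_eff`.

## Mean radiant temperature

Five estimation routes cover the possible sensor complements:

1. **globe** — forced-convection globe equation,
   T_mrt = [(T_g+273.15)⁴ + 1.1·10⁸ v^0.6/(ε_g D^0.4)·(T_g − T_a)]^¼ − 273.15,
   with a 0.05 m, ε_g = 0.95 matte-black globe by default. With extreme
   inputs the bracket can go negative; it is clamped at 0 K with a runtime
   warning rather than returning a complex number.
2. **ir_l_sphere** / 3. **ir_l_person** — one-directional radiant flux
   S_str = F·α_k·SW + ε_p·LW with F = 0.167 (sphere) or 0.06 (standing
   person), α_k = 0.7, ε_p = 0.97, then T_mrt = (S_str/(ε_p σ))^¼ − 273.15.
   With SW = 0 the ε_p factors cancel and both collapse to the brightness
   temperature.
4. **ir_only** — T_mrt = T_IRT = (LW/σ)^¼ − 273.15 (blackbody law, no
   emissivity correction: this is a brightness temperature by construction).
5. **air_temperature** — T_mrt = T_a, the indoor fallback.

`globe_from_mrt` inverts route 1 by Brent root finding on T_g ∈ [−60, 120] °C
(residual < 10⁻⁶); it exists to construct synthetic globe channels from a
known radiant field and to serve as a round-trip oracle, and the round trip
closes to better than 10⁻⁵ K across T_mrt ∈ [0, 60], T_a ∈ [10, 40],
v ∈ [0.1, 5]. No small-globe-to-standard-globe conversion is applied: the
globe constants describe the device's own globe.

## PET and the MEMI balance

The body model is a steady-state three-node (core, skin, clothing) energy
balance. Per unit DuBois area (A_Du = 0.203·m^0.425·h^0.725):

* **Core:** metabolic heat (work metabolism + a Harris-Benedict-type basal
  rate depending on sex, age, height, weight) plus sensible and latent
  respiratory fluxes equals the heat carried to the skin by skin blood flow
  (vasomotor-controlled, 6.3–90 L m⁻² h⁻¹, blood heat capacity
  3640 J kg⁻¹ K⁻¹) plus tissue conduction (5.28 W m⁻² K⁻¹).
* **Skin:** that influx leaves by radiation and convection of the bare
  fraction, by evaporation (regulatory sweat, 304.94 g m⁻² h⁻¹ per K of
  mean-body-temperature excess over 36.34 °C, capped at 500 g m⁻² h⁻¹ and
  by the wet-skin maximum; plus passive diffusion through a Woodcock
  vapor resistance with permeability index i_m = 0.38), and by conduction
  into the clothing layer, modelled as a cylindrical shell.
* **Clothing:** the conducted flux leaves by radiation and convection of
  the clothed fraction.

The convection coefficient is the seated-person form
h_c = 2.67 + 6.5·v^0.67 W m⁻² K⁻¹; the effective radiating fraction is
0.725; skin and clothing emissivities are 0.99 and 0.95. The clothed area
fraction follows the cubic f_acl(clo) fit and the clothing area factor
f_cl = 1 + 0.31·clo. Because the clothing geometry degenerates as clo → 0,
the model requires clo ≥ 0.1; the default person wears 0.9 clo.

The system is solved by hybrid-Powell root finding from the fixed initial
state (37, 34, (T_a+T_mrt)/2) °C; a solution is accepted only if every
nodal residual is below 10⁻³ W m⁻², otherwise an error carrying the last
residuals is raised. The solve is fully deterministic.

**PET** is then the air temperature of the reference environment
(T_mrt = T_a = PET, v = 0.1 m s⁻¹, ρ_v = 12 hPa, 0.9 clo, 80 W work
metabolism, same body) that closes the energy balance with the actual
body state held fixed: the summed nodal residual is driven to zero by
Brent search over [−60, 90] °C with 0.01 K tolerance. Holding the full
state and zeroing the summed balance is the equivalence criterion of the
published script this formulation follows; in the reference environment
itself it makes PET reproduce the input air temperature exactly. The sweat
cap, wet-skin clamp and vasomotor saturation make the summed balance
monotone in practice; a bracket failure raises an error suggesting a wider
range. One stated consequence of the fixed-state criterion together with
the Woodcock diffusion term is that neutral-condition skin temperatures sit
near 28 °C under 0.9 clo — cooler than the 33–34 °C most two-node models
report, but consistent with the formulation adopted here (an independent
transcription of the same equations, solved by a different numerical route,
agrees to ≤ 0.1 K on a 50-point grid; see `tests/_synthetic_pet_oracle.py`).

**Classification.** PET maps to nine stress levels with boundaries at
4, 8, 13, 18, 23, 29, 35 and 41 °C. Printed range tables are ambiguous at
the boundaries, so intervals are left-closed/right-open, deterministically:
[18, 23) is "no thermal stress", and 41.0 itself is already "extreme heat
stress" (a measure-zero deviation from a literal "> 41"). English labels
are canonical; German and French display tables are provided.

## Calibration and evaluation

Per-channel, per-device calibration is ordinary least squares of reference
on raw, optionally excluding pairs above a saturation cutoff; applying a
calibration outside its fitted range flags, never rejects. Error metrics
use the test-minus-reference sign convention (MBE < 0 means the device
underestimates). Light-binned difference summaries use the device's own lux
channel with bins {0 lx}, (0, 500], (500, ∞) and Tukey 1.5·IQR whiskers
(the whisker convention is this package's choice). Stress frequencies are
reported over the full period and over the half-open working-hours window
[08:00, 18:00) UTC. Series alignment is nearest-neighbour within ±2.5 min,
reference series driving the pairing, each record used at most once —
instantaneous values are paired, not window averages.

## Synthetic scenarios

The generator emulates diurnal office/industrial deployments on a 5-min
grid: sinusoidal T_a (default mean 24 °C, amplitude 3 K, 15:00 UTC peak),
RH anti-correlated with T_a, a half-sine window-sun SW pulse (east-office
preset: 06:00–10:00 UTC, 400 W m⁻² peak, kept below the lux saturation so
the light channel stays invertible), longwave from a wall-temperature model
LW = σ(T_a + ΔT_wall + 273.15)⁴, and constant waste-heat offsets for the
industrial preset. Ground-truth T_mrt is defined through the sphere-weighted
radiant flux of those fields, and the globe channel is generated with
`globe_from_mrt`, so with noise off both the globe and the IR+light routes
recover the truth exactly — end-to-end determinism that the tests exploit.
Per-channel Gaussian noise defaults (T_a 0.3 K, RH 2 %, T_g 0.3 K, LW
5 W m⁻², light 5 % multiplicative) are at low-cost-sensor datasheet scale.
Semi-outdoor wind is log-normal with a 0.5 m s⁻¹ cup-anemometer starting
deadband applied before the 0.1 m s⁻¹ floor.

What the generator does **not** emulate: radiative-transfer or
building-energy physics, sensor drift and response lags, radiation error on
the T_a screen, occupancy effects, or weather variability beyond the single
diurnal harmonic. Passing tests therefore demonstrate the correctness and
internal consistency of the computation chain under known ground truth, not
field accuracy of any particular hardware.

## Problem sizes and numerical choices

The evaluation scenario used by `scripts/acceptance.py` is two weeks at
5-min device / 10-min reference cadence (4032 device records, 2016 aligned
pairs) — the scale of a typical instrument-comparison campaign. Root
finders: Brent (bracketed) for all scalar inversions; hybrid Powell for the
3-node system; fixed initial states and fixed seeds everywhere, so all
outputs are bit-reproducible. CSV output rounds to 3 decimals, the declared
round-trip precision. Configuration is validated by dataclass constructors
(plain `__post_init__` checks) rather than an external schema library.

## Known limitations

* PET is computed per record by a scalar solve (~0.5 ms each); very long
  archives should be processed in chunks or downsampled.
* The MEMI formulation is steady-state: rapid transients (door openings,
  passing clouds) are treated as a sequence of equilibria.
* The lux→SW slope is spectrum-dependent; indoor artificial lighting with a
  different spectrum than daylight will bias the IR+light T_mrt routes.
* Calibration is linear per channel; nonlinear sensor response outside the
  fitted range is only flagged, not corrected.
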