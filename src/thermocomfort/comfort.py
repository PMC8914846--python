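"""PET via the MEMI human energy balance, and stress classification.

The physiologically equivalent temperature (PET) of an environment is the
air temperature of a reference indoor setting (T_mrt = T_a, v = 0.1 m/s,
vapor pressure 12 hPa, clothing 0.9 clo, light activity 80 W) in which a
standardized person attains the same body thermal state as in the actual
environment.

The body model is the MEMI three-node (core / skin / clothing) steady-state
energy balance: metabolic heat and respiratory fluxes load the core; blood
flow and tissue conduction couple core to skin; the skin exchanges by
radiation, convection, vapor diffusion and sweat evaporation, partly
through a cylindrical clothing layer.  The three nodal balances are solved
simultaneously; PET is then the scalar root of the summed balance of the
reference environment with the body state held fixed.

Numerical route: damped multidimensional root finding (``scipy.optimize.root``,
hybrid Powell) from the fixed initial state (37 / 34 / mean(T_a, T_mrt)) degC
for the body state, then bracketed Brent search over [-60, 90] degC for PET.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .mrt import GlobeSpec, MrtEstimate, estimate_mrt
from .radiation import RadiationConstants
from .records import saturation_vapor_pressure

__all__ = [
    "PersonConfig",
    "ThermalState",
    "ComfortResult",
    "STRESS_LEVELS",
    "STRESS_BOUNDS_C",
    "solve_energy_balance",
    "pet",
    "classify_pet",
    "comfort_pipeline",
    "compute_frame",
    "EnergyBalanceError",
]

# ---------------------------------------------------------------------------
# model constants

SIGMA = 5.67e-8            # Stefan-Boltzmann [W m-2 K-4]
EPS_SKIN = 0.99            # skin emissivity
EPS_CLO = 0.95             # clothing emissivity
H_VAP = 2.42e6             # latent heat of vaporization [J/kg]
C_BLOOD = 3640.0           # blood specific heat [J/(kg K)]
C_AIR = 1010.0             # air specific heat [J/(kg K)]
P_ATM_HPA = 1013.25        # total pressure [hPa]
LEWIS_K_PER_HPA = 1.67     # Lewis ratio [K/hPa]
I_M = 0.38                 # Woodcock moisture permeability index
T_CORE_SET = 36.6          # core set point [degC]
T_SKIN_SET = 34.0          # skin set point [degC]
T_BODY_SET = 0.1 * T_SKIN_SET + 0.9 * T_CORE_SET  # 36.34 degC
SWEAT_G_PER_M2H_K = 304.94  # sweat rate gain [g/(m2 h K)]
SWEAT_MAX_G_PER_M2H = 500.0
BLOOD_FLOW_MAX = 90.0      # [L/(m2 h)]
TISSUE_CONDUCTANCE = 5.28  # core-skin conduction [W/(m2 K)]

#: reference-environment definition
REF_WIND_MS = 0.1
REF_VP_HPA = 12.0
REF_CLO = 0.9
REF_WORK_W = 80.0

STRESS_BOUNDS_C = (4.0, 8.0, 13.0, 18.0, 23.0, 29.0, 35.0, 41.0)

#: nine thermophysiological stress levels, cold to hot
STRESS_LEVELS = (
    "extreme cold stress",
    "strong cold stress",
    "moderate cold stress",
    "slight cold stress",
    "no thermal stress",
    "slight heat stress",
    "moderate heat stress",
    "strong heat stress",
    "extreme heat stress",
)

#: display translations keyed by language code (en labels are canonical)
STRESS_LABELS = {
    "en": STRESS_LEVELS,
    "de": (
        "extreme Kältebelastung",
        "starke Kältebelastung",
        "mäßige Kältebelastung",
        "leichte Kältebelastung",
        "keine thermische Belastung",
        "leichte Wärmebelastung",
        "mäßige Wärmebelastung",
        "starke Wärmebelastung",
        "extreme Wärmebelastung",
    ),
    "fr": (
        "stress froid extrême",
        "stress froid fort",
        "stress froid modéré",
        "stress froid léger",
        "pas de stress thermique",
        "stress chaud léger",
        "stress chaud modéré",
        "stress chaud fort",
        "stress chaud extrême",
    ),
}


class EnergyBalanceError(RuntimeError):
    """The MEMI system or the PET search failed to converge."""


@dataclass(frozen=True)
class PersonConfig:
    """Body, clothing and activity of the modelled person.

    Defaults are the standardized person: male, 35 years, 1.75 m, 75 kg,
    0.9 clo (business suit) and 80 W work metabolism (light activity).
    """

    sex: str = "male"
    age: float = 35.0
    height_m: float = 1.75
    weight_kg: float = 75.0
    clothing_clo: float = 0.9
    work_metabolism_w: float = 80.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not 0.5 < self.height_m < 2.5:
            raise ValueError("height must be in (0.5, 2.5) m")
        if not 20.0 < self.weight_kg < 200.0:
            raise ValueError("weight must be in (20, 200) kg")
        if self.clothing_clo < 0.1:
            raise ValueError("clothing below 0.1 clo is outside the clothed body model")
        if self.work_metabolism_w < 0:
            raise ValueError("work metabolism must be >= 0 W")

    @property
    def body_surface_m2(self) -> float:
        """DuBois body surface area [m2]."""
        return 0.203 * self.weight_kg**0.425 * self.height_m**0.725

    @property
    def basal_metabolism_w(self) -> float:
        """Harris-Benedict-type basal heat production [W]."""
        w, h_cm, a = self.weight_kg, self.height_m * 100.0, self.age
        if self.sex == "male":
            return 3.45 * w**0.75 * (1 + 0.004 * (30 - a) + 0.010 * (h_cm / w ** (1 / 3) - 43.4))
        return 3.19 * w**0.75 * (1 + 0.004 * (30 - a) + 0.018 * (h_cm / w ** (1 / 3) - 42.1))


@dataclass(frozen=True)
class ThermalState:
    """Solved MEMI node temperatures [degC]."""

    t_core: float
    t_skin: float
    t_clothing: float
    residuals: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0), compare=False)


def _skin_blood_flow(t_core: float, t_skin: float) -> tuple[float, float]:
    """Vasomotor skin blood flow [L/(m2 h)] and core/skin mixing factor alpha."""
    sig_core = max(t_core - T_CORE_SET, 0.0)
    sig_skin = max(T_SKIN_SET - t_skin, 0.0)
    m_blood = min((6.3 + 75.0 * sig_core) / (1.0 + 0.5 * sig_skin), BLOOD_FLOW_MAX)
    alpha = 0.0417737 + 0.7451833 / (m_blood + 0.585417)
    return m_blood, alpha


def _sweat_rate(t_body: float) -> float:
    """Regulatory sweat rate [g/(m2 h)] from mean body temperature."""
    sig_body = max(t_body - T_BODY_SET, 0.0)
    return min(SWEAT_G_PER_M2H_K * sig_body, SWEAT_MAX_G_PER_M2H)


def _clothing_geometry(person: PersonConfig, clo: float) -> dict:
    """Clothed-fraction geometry of the cylindrical clothing model."""
    a_du = person.body_surface_m2
    facl = (173.51 * clo - 2.36 - 100.76 * clo**2 + 19.28 * clo**3) / 100.0
    facl = min(facl, 1.0)
    fcl = 1.0 + 0.31 * clo               # clothing area factor
    feff = 0.725                          # effective radiating fraction (seated/standing)
    a_clo = a_du * facl + a_du * (fcl - 1.0)
    a_eff = a_du * feff
    r_cl = clo / 6.45                     # insulation [m2 K / W]
    if clo >= 2.0:
        y = 1.0
    elif clo > 0.6:
        y = (person.height_m - 0.2) / person.height_m
    elif clo > 0.3:
        y = 0.5
    else:
        y = 0.1
    circ = 2.0 * math.pi * person.height_m * y
    r2 = a_du * (fcl - 1.0 + facl) / circ   # outer clothing radius [m]
    r1 = facl * a_du / circ                 # inner radius [m]
    htcl = circ * (r2 - r1) / (r_cl * math.log(r2 / r1) * a_clo)  # [W/(m2 K)]
    return {"a_du": a_du, "facl": facl, "fcl": fcl, "a_clo": a_clo, "a_eff": a_eff, "r_cl": r_cl, "htcl": htcl}


def energy_balance_residuals(
    state: tuple[float, float, float],
    ta: float,
    vp: float,
    tmrt: float,
    v: float,
    person: PersonConfig,
    clo: float | None = None,
    work_w: float | None = None,
) -> tuple[float, float, float]:
    """Residuals [W/m2] of the core, skin and clothing balances at ``state``.

    ``clo`` / ``work_w`` default to the person's own clothing and activity;
    the PET reference search overrides them with the reference values.
    """
    t_cr, t_sk, t_clo = state
    clo = person.clothing_clo if clo is None else clo
    work_w = person.work_metabolism_w if work_w is None else work_w
    g = _clothing_geometry(person, clo)
    a_du = g["a_du"]

    # internal heat per unit body area
    met = work_w + person.basal_metabolism_w
    he = met / a_du

    # convection coefficient (seated person), pressure-corrected
    hc = (2.67 + 6.5 * v**0.67) * (P_ATM_HPA / P_ATM_HPA) ** 0.55

    # respiration: sensible + latent loss via pulmonary ventilation
    t_exp = 0.47 * ta + 21.0
    d_vent = he * 1.44e-6  # [kg/(s m2)]
    c_res = C_AIR * (ta - t_exp) * d_vent
    vp_exp = saturation_vapor_pressure(t_exp)
    q_res = 0.623 * H_VAP / P_ATM_HPA * (vp - vp_exp) * d_vent
    ere = c_res + q_res

    # vasomotor regulation and mean body temperature
    m_blood, alpha = _skin_blood_flow(t_cr, t_sk)
    t_body = alpha * t_sk + (1.0 - alpha) * t_cr

    # evaporation: regulatory sweat, capped by the wet-skin maximum,
    # plus passive diffusion through skin and clothing (Woodcock)
    vp_skin = saturation_vapor_pressure(t_sk)
    he_diff = hc * LEWIS_K_PER_HPA
    fecl = 1.0 / (1.0 + 0.92 * hc * g["r_cl"])
    e_max = he_diff * fecl * (vp_skin - vp)
    esw = H_VAP / 1000.0 * _sweat_rate(t_body) / 3600.0  # [W/m2]
    if e_max <= 0.0:
        esw, w = 0.0, 0.0
    else:
        w = esw / e_max
        if w > 1.0:
            w, esw = 1.0, e_max
    r_ecl = (1.0 / (g["fcl"] * hc) + g["r_cl"]) / (LEWIS_K_PER_HPA * I_M)
    e_diff = (1.0 - w) * (vp_skin - vp) / r_ecl
    evap = -(e_diff + esw)

    # radiation and convection, split into bare and clothed fractions
    tr_k4 = (tmrt + 273.15) ** 4
    r_bare = g["a_eff"] * (1.0 - g["facl"]) * EPS_SKIN * SIGMA * (tr_k4 - (t_sk + 273.15) ** 4) / a_du
    r_clo = 0.725 * g["a_clo"] * EPS_CLO * SIGMA * (tr_k4 - (t_clo + 273.15) ** 4) / a_du
    c_bare = hc * (ta - t_sk) * (1.0 - g["facl"])
    c_clo = hc * (ta - t_clo) * g["a_clo"] / a_du

    # core-to-skin transport: blood flow + tissue conduction
    k_body = m_blood / 3600.0 * C_BLOOD + TISSUE_CONDUCTANCE

    core = he + ere - k_body * (t_cr - t_sk)
    skin = r_bare + c_bare + evap + k_body * (t_cr - t_sk) - g["htcl"] * (t_sk - t_clo)
    cloth = r_clo + c_clo + g["htcl"] * (t_sk - t_clo)
    return core, skin, cloth


def solve_energy_balance(
    ta: float,
    vp: float,
    tmrt: float,
    v_eff: float,
    person: PersonConfig | None = None,
    clo: float | None = None,
    work_w: float | None = None,
) -> ThermalState:
    """Solve the three-node MEMI balance for the body thermal state.

    Deterministic: fixed initial state (37 / 34 / mean(ta, tmrt)) degC and
    a damped hybrid-Powell root.  Raises :class:`EnergyBalanceError` with
    the last residuals if the system does not converge below 1e-3 W/m2.
    """
    if person is None:
        person = PersonConfig()
    if v_eff < REF_WIND_MS:
        raise ValueError("v_eff must be >= 0.1 m/s (apply the wind floor first)")

    def fun(x):
        return energy_balance_residuals(tuple(x), ta, vp, tmrt, v_eff, person, clo, work_w)

    x0 = np.array([37.0, 34.0, 0.5 * (ta + tmrt)])
    sol = root(fun, x0, method="hybr", tol=1e-10)
    res = fun(sol.x)
    if not sol.success or max(abs(r) for r in res) > 1e-3:
        raise EnergyBalanceError(
            f"MEMI balance did not converge for ta={ta}, vp={vp}, tmrt={tmrt}, "
            f"v={v_eff}; residuals={res}"
        )
    return ThermalState(float(sol.x[0]), float(sol.x[1]), float(sol.x[2]), tuple(float(r) for r in res))


def pet(
    ta: float,
    vp: float,
    tmrt: float,
    v_eff: float,
    person: PersonConfig | None = None,
) -> float:
    """Physiologically equivalent temperature [degC].

    Solves the actual environment for the body state, then finds the
    reference-environment air temperature (T_mrt equal to it, v = 0.1 m/s,
    vapor pressure 12 hPa, 0.9 clo, 80 W activity) at which the summed
    energy balance of that fixed body state closes.  Brent search over
    [-60, 90] degC, tolerance 0.01 K.
    """
    if person is None:
        person = PersonConfig()
    state = solve_energy_balance(ta, vp, tmrt, v_eff, person)
    x = (state.t_core, state.t_skin, state.t_clothing)

    def g(tx: float) -> float:
        return sum(
            energy_balance_residuals(
                x, tx, REF_VP_HPA, tx, REF_WIND_MS, person, clo=REF_CLO, work_w=REF_WORK_W
            )
        )

    lo, hi = -60.0, 90.0
    if g(lo) * g(hi) > 0:
        raise EnergyBalanceError(
            f"PET not bracketed in [{lo}, {hi}] degC for ta={ta}, vp={vp}, tmrt={tmrt}, "
            "v={v_eff}; widen the search range"
        )
    return float(brentq(g, lo, hi, xtol=0.01))


def classify_pet(pet_c: float) -> str:
    """Nine-level thermophysiological stress class of a PET value.

    Boundaries at 4, 8, 13, 18, 23, 29, 35, 41 degC; intervals left-closed
    right-open, so e.g. [18, 23) is "no thermal stress" and 41.0 itself is
    already "extreme heat stress".
    """
    if not np.isfinite(pet_c):
        raise ValueError("PET must be finite")
    idx = int(np.searchsorted(STRESS_BOUNDS_C, pet_c, side="right"))
    return STRESS_LEVELS[idx]


@dataclass(frozen=True)
class ComfortResult:
    """Full output of the comfort chain for one record."""

    tmrt: MrtEstimate
    pet_c: float
    stress_level: str
    vp_hpa: float
    v_eff_ms: float


def comfort_pipeline(
    record,
    method: str = "globe",
    person: PersonConfig | None = None,
    constants: RadiationConstants | None = None,
    globe: GlobeSpec | None = None,
) -> ComfortResult:
    """Chain T_mrt estimation -> PET -> stress class for one derived record.

    Errors from a stage propagate with the stage named in the message.
    """
    if person is None:
        person = PersonConfig()
    est = estimate_mrt(record, method, constants, globe)
    vp = float(record["vp_hpa"])
    v_eff = float(record["v_eff_ms"])
    try:
        pet_c = pet(float(record["ta_c"]), vp, est.tmrt_c, v_eff, person)
    except EnergyBalanceError as exc:
        raise EnergyBalanceError(f"pet stage: {exc}") from exc
    return ComfortResult(est, pet_c, classify_pet(pet_c), vp, v_eff)


def compute_frame(
    df: pd.DataFrame,
    method: str = "globe",
    person: PersonConfig | None = None,
    constants: RadiationConstants | None = None,
    globe: GlobeSpec | None = None,
) -> pd.DataFrame:
    """Add ``pet_c`` and ``stress_level`` columns to an mrt-enriched frame.

    ``tmrt_<method>_c`` must already be present (see
    :func:`thermocomfort.mrt.add_mrt_columns`); row order is preserved.
    """
    if person is None:
        person = PersonConfig()
    col = f"tmrt_{method}_c"
    if col not in df.columns:
        raise KeyError(f"frame lacks {col}; run add_mrt_columns first")
    out = df.copy()
    pets = np.empty(len(out))
    for i, (ta, vp, tmrt, v) in enumerate(
        zip(out["ta_c"], out["vp_hpa"], out[col], out["v_eff_ms"])
    ):
        pets[i] = pet(float(ta), float(vp), float(tmrt), float(v), person)
    out["pet_c"] = pets
    out["stress_level"] = [classify_pet(p) for p in pets]
    return out
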