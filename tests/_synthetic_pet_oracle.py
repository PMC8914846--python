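"""Synthetic stand-in oracle for the steady-state PET computation.

This is an independent, deliberately plain transcription of the published
MEMI three-node PET formulation, kept free of any import from the
``thermocomfort`` package and solved with a different numerical route
(``scipy.optimize.fsolve`` for both the body state and the PET scalar,
warm-started from the clothing temperature) so it can serve as a
dual-route cross-check of the production implementation.  It is a
constructed stand-in, not the original authors' script.
"""

import math

import numpy as np
from scipy.optimize import fsolve


def _esat_hpa(t):
    # Magnus over water, WMO constants
    return 6.112 * math.exp(17.62 * t / (243.12 + t))


def _balance(temps, Tair, VP, Tmrt, vel, Mact, clo, weight, height, age, sex):
    Tc, Tsk, Tcl = temps
    sbc = 5.67e-8
    Adu = 0.203 * weight**0.425 * height**0.725
    if sex == "male":
        M0 = 3.45 * weight**0.75 * (1 + 0.004 * (30 - age) + 0.01 * (height * 100 / weight ** (1 / 3) - 43.4))
    else:
        M0 = 3.19 * weight**0.75 * (1 + 0.004 * (30 - age) + 0.018 * (height * 100 / weight ** (1 / 3) - 42.1))
    H = (Mact + M0) / Adu

    # respiration
    Tex = 0.47 * Tair + 21.0
    vent = H * 1.44e-6
    Cres = 1010.0 * (Tair - Tex) * vent
    Eres = 0.623 * 2.42e6 / 1013.25 * (VP - _esat_hpa(Tex)) * vent

    # vasomotricity
    dc = max(Tc - 36.6, 0.0)
    ds = max(34.0 - Tsk, 0.0)
    mblood = min((6.3 + 75.0 * dc) / (1.0 + 0.5 * ds), 90.0)
    alpha = 0.0417737 + 0.7451833 / (mblood + 0.585417)
    Tbody = alpha * Tsk + (1 - alpha) * Tc

    # clothing geometry
    facl = min((173.51 * clo - 2.36 - 100.76 * clo**2 + 19.28 * clo**3) / 100.0, 1.0)
    fcl = 1 + 0.31 * clo
    Aclo = Adu * facl + Adu * (fcl - 1)
    feff = 0.725
    Rcl = clo / 6.45
    if clo >= 2:
        y = 1.0
    elif clo > 0.6:
        y = (height - 0.2) / height
    elif clo > 0.3:
        y = 0.5
    else:
        y = 0.1
    circ = 2 * math.pi * height * y
    r2 = Adu * (fcl - 1 + facl) / circ
    r1 = facl * Adu / circ
    htcl = circ * (r2 - r1) / (Rcl * math.log(r2 / r1) * Aclo)

    hc = 2.67 + 6.5 * vel**0.67

    # sweat + diffusion
    sw = min(304.94 * max(Tbody - 36.34, 0.0), 500.0)
    Esw = 2.42e6 / 1000.0 * sw / 3600.0
    vpsk = _esat_hpa(Tsk)
    Lw = 1.67
    fecl = 1 / (1 + 0.92 * hc * Rcl)
    Emax = hc * Lw * fecl * (vpsk - VP)
    if Emax <= 0:
        Esw, wet = 0.0, 0.0
    else:
        wet = Esw / Emax
        if wet > 1:
            wet, Esw = 1.0, Emax
    Recl = (1 / (fcl * hc) + Rcl) / (Lw * 0.38)
    Ediff = (1 - wet) * (vpsk - VP) / Recl

    # radiation / convection split
    Rbare = 0.725 * Adu * (1 - facl) * 0.99 * sbc * ((Tmrt + 273.15) ** 4 - (Tsk + 273.15) ** 4) / Adu
    Rclo = feff * Aclo * 0.95 * sbc * ((Tmrt + 273.15) ** 4 - (Tcl + 273.15) ** 4) / Adu
    Cbare = hc * (Tair - Tsk) * (1 - facl)
    Cclo = hc * (Tair - Tcl) * Aclo / Adu

    K = mblood / 3600.0 * 3640.0 + 5.28
    eq_core = H + Cres + Eres - K * (Tc - Tsk)
    eq_skin = Rbare + Cbare - (Ediff + Esw) + K * (Tc - Tsk) - htcl * (Tsk - Tcl)
    eq_clo = Rclo + Cclo + htcl * (Tsk - Tcl)
    return eq_core, eq_skin, eq_clo


def pet_oracle(Tair, VP, Tmrt, vel, Mact=80.0, clo=0.9,
               weight=75.0, height=1.75, age=35.0, sex="male"):
    """Stand-in PET [degC] for the given actual environment."""
    body = (weight, height, age, sex)
    state = fsolve(
        lambda x: _balance(x, Tair, VP, Tmrt, vel, Mact, clo, *body),
        np.array([36.7, 34.0, 0.5 * (Tair + Tmrt)]),
        full_output=False,
    )

    def ref_balance(tx):
        eqs = _balance(state, float(tx[0]), 12.0, float(tx[0]), 0.1, 80.0, 0.9, *body)
        return [sum(eqs)]

    pet_val = fsolve(ref_balance, np.array([state[2]]))
    return float(pet_val[0]), tuple(float(t) for t in state)
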