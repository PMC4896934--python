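"""Blood gas transport: dissociation curves, alveolar and tissue balances.

Blood O₂ content follows a Hill saturation curve with a dissolved term;
blood CO₂ content a monotone power law anchored at the arterial norm
(48 ml/dl at 40 mmHg, slope 0.66 ml/dl/mmHg).  Both are strictly increasing
over the physiological range so the forward (P→C) and inverse (C→P) maps are
exact functional inverses.

The alveolar compartment is a single well-mixed space: its gas tensions obey
a mass balance where the effective capacitance is the alveolar gas volume
plus the blood-side storage ``863·Vap·dC/dP`` of the pulmonary arterial
blood equilibrating with it.  ``863`` mmHg converts content flux (ml STPD
per ml blood) into partial-pressure–volume flux (BTPS); blood leaving the
lungs is assumed fully equilibrated with the alveoli.  During inspiration a
fresh-gas term ``V̇A·(P_I − P_alv)`` adds inspired air; during expiration it
is absent.

Tissue districts are well mixed too: venous content equals tissue content,
and each district consumes O₂ at its prescribed rate and produces CO₂ at
``RQ`` times that rate.

Public content functions use ml gas / dl blood; flows cm³/s; volumes of gas
in litres.
"""
from __future__ import annotations

import math

from ._compat import maybe_jit

__all__ = [
    "HB_CAPACITY", "P50", "HILL_N", "O2_SOLUBILITY",
    "o2_content", "o2_partial_pressure", "o2_slope",
    "co2_content", "co2_partial_pressure", "co2_slope",
    "alveolar_derivatives", "arterial_mixing", "tissue_derivatives",
]

# O2 curve constants (model constants of this implementation)
HB_CAPACITY = 20.1    # ml O2/dl blood bound at full saturation
P50 = 26.6            # mmHg at half saturation
HILL_N = 2.7          # Hill cooperativity
O2_SOLUBILITY = 0.003  # ml O2/dl/mmHg dissolved

# CO2 curve constants: content 48 ml/dl at the 40 mmHg arterial norm,
# local slope 0.66 ml/dl/mmHg (power law exponent 0.55).
CO2_REF_CONTENT = 48.0
CO2_REF_P = 40.0
CO2_EXPONENT = 0.55

#: mmHg; converts ml STPD gas per ml blood into BTPS partial-pressure volume.
K863 = 863.0


@maybe_jit
def o2_content(p_o2: float) -> float:
    """O2 content (ml/dl) of blood equilibrated at ``p_o2`` mmHg."""
    s = p_o2 ** HILL_N
    return HB_CAPACITY * s / (P50 ** HILL_N + s) + O2_SOLUBILITY * p_o2


@maybe_jit
def o2_slope(p_o2: float) -> float:
    """dC/dP of the O2 curve, ml/dl/mmHg."""
    pn = p_o2 ** HILL_N
    k = P50 ** HILL_N
    return HB_CAPACITY * HILL_N * k * pn / (p_o2 * (k + pn) ** 2) + O2_SOLUBILITY


@maybe_jit
def _o2_pp_core(c: float) -> float:
    # Newton with bisection safeguard on [1e-9, 5000] mmHg.
    lo, hi = 1.0e-9, 5000.0
    p = 40.0
    for _ in range(100):
        f = o2_content(p) - c
        if f > 0.0:
            hi = p
        else:
            lo = p
        step = f / o2_slope(p)
        p_new = p - step
        if p_new <= lo or p_new >= hi:
            p_new = 0.5 * (lo + hi)
        if abs(p_new - p) < 1.0e-10:
            return p_new
        p = p_new
    return p


def o2_partial_pressure(c_o2: float) -> float:
    """Inverse of :func:`o2_content` (exact within 1e-6 mmHg)."""
    if not 0.0 <= c_o2 < o2_content(5000.0):
        raise ValueError(f"O2 content {c_o2!r} ml/dl outside curve range")
    if c_o2 == 0.0:
        return 0.0
    return _o2_pp_core(c_o2)


@maybe_jit
def co2_content(p_co2: float) -> float:
    """CO2 content (ml/dl) of blood at ``p_co2`` mmHg."""
    return CO2_REF_CONTENT * (p_co2 / CO2_REF_P) ** CO2_EXPONENT


@maybe_jit
def co2_slope(p_co2: float) -> float:
    return CO2_EXPONENT * co2_content(p_co2) / p_co2


def co2_partial_pressure(c_co2: float) -> float:
    """Inverse of :func:`co2_content` (analytic)."""
    if c_co2 < 0.0:
        raise ValueError(f"CO2 content {c_co2!r} ml/dl outside curve range")
    return _co2_pp_core(c_co2)


@maybe_jit
def _co2_pp_core(c: float) -> float:
    return CO2_REF_P * (c / CO2_REF_CONTENT) ** (1.0 / CO2_EXPONENT)


@maybe_jit
def arterial_mixing(c_pulmonary_end: float, c_mixed_venous: float, ps: float) -> float:
    """Systemic arterial content after venous admixture through the shunt ``ps``."""
    return (1.0 - ps) * c_pulmonary_end + ps * c_mixed_venous


@maybe_jit
def _alveolar_gas_rate(p_alv, c_ven, v_alv, vap_l, qpv_ls, vdot_a, p_insp,
                       ps, c_eq, slope, inspiration):
    # contents ml/ml, slope ml/ml/mmHg, volumes l, flows l/s
    uptake = K863 * (1.0 - ps) * qpv_ls * (c_ven - c_eq)
    fresh = vdot_a * (p_insp - p_alv) if inspiration else 0.0
    cap = v_alv + K863 * vap_l * slope
    return (uptake + fresh) / cap


@maybe_jit
def alveolar_derivatives(p_o2alv: float, p_co2alv: float, v_alv: float,
                         vap_cm3: float, qpv_cm3s: float,
                         c_o2vp: float, c_co2vp: float,
                         vdot_a: float, inspiration: bool,
                         p_o2i: float, p_co2i: float, ps: float):
    """Rates of change of alveolar O2/CO2 tensions (mmHg/s).

    Parameters use the engine's native units: ``v_alv`` alveolar gas volume
    (l; end-expiratory volume plus the incremental alveolar volume during
    inspiration, end-inspiratory based during expiration), ``vap_cm3``
    instantaneous pulmonary arterial blood volume, ``qpv_cm3s`` pulmonary
    blood flow, contents ml/dl (mixed venous entering the lungs), ``vdot_a``
    alveolar ventilation l/s (>= 0), ``inspiration`` selects the fresh-gas
    term.
    """
    qpv_ls = max(qpv_cm3s, 0.0) * 1.0e-3
    vap_l = vap_cm3 * 1.0e-3
    d_o2 = _alveolar_gas_rate(
        p_o2alv, c_o2vp * 0.01, v_alv, vap_l, qpv_ls, vdot_a, p_o2i, ps,
        o2_content(p_o2alv) * 0.01, o2_slope(p_o2alv) * 0.01, inspiration)
    d_co2 = _alveolar_gas_rate(
        p_co2alv, c_co2vp * 0.01, v_alv, vap_l, qpv_ls, vdot_a, p_co2i, ps,
        co2_content(p_co2alv) * 0.01, co2_slope(p_co2alv) * 0.01, inspiration)
    return d_o2, d_co2


@maybe_jit
def tissue_derivatives(c_o2iv: float, c_co2iv: float,
                       c_o2ia: float, c_co2ia: float,
                       qia: float, vi: float, vo2: float, rq: float):
    """Rates of change of district venous contents (ml/dl per s).

    Well-mixed balance d(C·V)/dt = C_a·Q_in − C_v·Q_out ∓ V̇gas with venous
    content equal to tissue content; eliminating dV/dt = Q_in − Q_out gives
    dC/dt = (Q_in⁺·(C_a − C_v) ∓ V̇gas)/V.  ``qia`` cm³/s (inflow; reverse
    flow carries district content and cancels), ``vi`` district blood volume
    cm³, ``vo2`` ml O2/min consumed, ``rq`` the respiratory quotient.
    """
    q = max(qia, 0.0)
    vdot = vo2 / 60.0 * 100.0  # ml/min -> (ml/dl scale)/s given volumes in cm3
    d_o2 = (q * (c_o2ia - c_o2iv) - vdot) / vi
    d_co2 = (q * (c_co2ia - c_co2iv) + rq * vdot) / vi
    return d_o2, d_co2
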