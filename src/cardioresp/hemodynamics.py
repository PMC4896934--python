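"""Cardiac chambers and the closed systemic + pulmonary vascular network.

The heart is a four-chamber lumped model: atria are passive compliances;
each ventricle blends the time-varying-elastance systolic law
``P = E_max·(V − V0)`` with an exponential passive filling law
``P = a·e^{b·V} + c`` through a smooth activation waveform
``φ(t_c) = sin²(π·t_c/T_sys)`` (``T_sys = 0.3·√TC``), so the two printed
end-member relations are recovered exactly at φ=1 and φ=0.

The systemic tree has an ascending and a descending aortic compartment
joined by an inertial segment; the upper body branches off the ascending
compartment, kidneys, splanchnic bed and both legs off the descending one.
Venous return converges through the superior vena cava and through a
two-compartment inferior vena cava whose intrathoracic part is fed through a
Starling resistor (collapsible-tube flow limitation under high intrathoracic
pressure).  Heart valves and leg venous valves are ideal diodes; the leg
muscle pump is an intramuscular pressure at the 1 Hz cycling cadence that
squeezes the deep veins of each leg — it drives the venous outflow branch,
rectified by the leg venous valves, without loading the arterial inflow.

All pressures are gauge (atmosphere = 0); the intrathoracic compartments
(both atria and ventricles, ascending aorta, SVC, intrathoracic IVC, both
pulmonary compartments) additionally feel the pleural pressure ``Pintr``.
"""
from __future__ import annotations

import math

from ._compat import maybe_jit
from . import state as S
from .config import (  # noqa: F401  (index constants used below)
    I_CLA, I_CRA, I_VLV0, I_VRV0, I_AL, I_BL, I_CL, I_AR, I_BR, I_CR,
    I_RLI, I_RRI, I_RLO, I_RRO,
    I_RAA, I_LAA, I_CAA, I_RABD, I_LABD, I_CABD,
    I_CUB, I_CKID, I_CSP, I_CLL, I_CRL,
    I_RUBV_SET, I_RKIDV_SET, I_RSPV_SET, I_RLLV_SET, I_RRLV_SET,
    I_CSUP, I_RSUP, I_CINFEXT, I_CINFINT, I_RINFEXT, I_RINFINT,
    I_RCP, I_CAP, I_RAP, I_LAP, I_VAP0, I_RVP, I_CVP, I_VVP0,
)

__all__ = [
    "activation", "atrial_pressure", "ventricular_pressure", "valve_flow",
    "starling_resistor_flow", "muscle_pump_pressure", "circulation_derivatives",
]


@maybe_jit
def activation(t_c: float, tc: float) -> float:
    """Ventricular activation waveform φ ∈ [0, 1] over the cardiac cycle."""
    t_sys = 0.3 * math.sqrt(tc)
    if t_c < 0.0 or t_c >= t_sys:
        return 0.0
    s = math.sin(math.pi * t_c / t_sys)
    return s * s


@maybe_jit
def atrial_pressure(v: float, c: float, v0: float, pintr: float) -> float:
    """Passive atrial pressure (mmHg): (V − V0)/C + Pintr."""
    return (v - v0) / c + pintr


@maybe_jit
def ventricular_pressure(v: float, t_c: float, tc: float, elmax: float,
                         v0: float, a: float, b: float, c: float,
                         pintr: float) -> float:
    """Ventricular pressure blending systolic elastance and passive filling."""
    phi = activation(t_c, tc)
    p_act = elmax * (v - v0)
    p_pas = a * math.exp(b * v) + c
    return phi * p_act + (1.0 - phi) * p_pas + pintr


@maybe_jit
def valve_flow(p_up: float, p_down: float, r: float) -> float:
    """Ideal diode in series with resistance ``r``; never negative."""
    if p_up > p_down:
        return (p_up - p_down) / r
    return 0.0


@maybe_jit
def starling_resistor_flow(p_in: float, p_out: float, p_ext: float,
                           r: float) -> float:
    """Collapsible-tube flow: ohmic, flow-limited (waterfall), or collapsed."""
    if p_out >= p_ext:
        return max((p_in - p_out) / r, 0.0)
    if p_in > p_ext:
        return (p_in - p_ext) / r
    return 0.0


@maybe_jit
def muscle_pump_pressure(t: float, wl: float, pim_max: float):
    """Antiphase left/right intramuscular pressures (mmHg) at 1 Hz cycling."""
    s = math.sin(2.0 * math.pi * t)
    p_ll = pim_max * wl * (1.0 + s)
    p_rl = pim_max * wl * (1.0 - s)
    return p_ll, p_rl


@maybe_jit
def circulation_derivatives(x, dx, p,
                            elmax, ermax, tc,
                            r_uba, r_kida, r_spa, r_lla, r_rla,
                            r_ubv, r_kidv, r_spv, r_llv, r_rlv,
                            vub0, vkid0, vsp0, vll0, vrl0,
                            pintr, pim_ll, pim_rl):
    """Fill ``dx`` for the circulation states and return key flows/pressures.

    ``x``/``dx`` use the :mod:`cardioresp.state` layout; ``p`` is the packed
    parameter vector; the remaining arguments are the instantaneous
    controlled (effective) parameter values.  By construction the volume
    derivatives sum to zero: the loop conserves blood exactly.

    Returns ``(q_av, q_ub, q_kid, q_sp, q_ll, q_rl, qv_ub, qv_kid, qv_sp,
    qv_ll, qv_rl, q_pa, paa_trans, p_ra, map_gauge)``.
    """
    t_c = x[S.TCPH]

    # --- pressures -------------------------------------------------------
    p_la = atrial_pressure(x[S.VLA], p[I_CLA], 0.0, pintr)
    p_ra = atrial_pressure(x[S.VRA], p[I_CRA], 0.0, pintr)
    p_lv = ventricular_pressure(x[S.VLV], t_c, tc, elmax, p[I_VLV0],
                                p[I_AL], p[I_BL], p[I_CL], pintr)
    p_rv = ventricular_pressure(x[S.VRV], t_c, tc, ermax, p[I_VRV0],
                                p[I_AR], p[I_BR], p[I_CR], pintr)

    paa_trans = x[S.VAA] / p[I_CAA]          # baroreflex input: no Pintr
    p_aa = paa_trans + pintr
    p_abd = x[S.VABD] / p[I_CABD]
    p_ub = (x[S.VUB] - vub0) / p[I_CUB]
    p_kid = (x[S.VKID] - vkid0) / p[I_CKID]
    p_sp = (x[S.VSP] - vsp0) / p[I_CSP]
    p_ll = (x[S.VLL] - vll0) / p[I_CLL]
    p_rl = (x[S.VRL] - vrl0) / p[I_CRL]
    p_sup = x[S.VSUP] / p[I_CSUP] + pintr
    p_infe = x[S.VINFE] / p[I_CINFEXT]
    p_infi = x[S.VINFI] / p[I_CINFINT] + pintr
    p_ap = (x[S.VAP] - p[I_VAP0]) / p[I_CAP] + pintr
    p_vp = (x[S.VVP] - p[I_VVP0]) / p[I_CVP] + pintr

    # --- flows -----------------------------------------------------------
    q_mit = valve_flow(p_la, p_lv, p[I_RLI])
    q_av = valve_flow(p_lv, p_aa, p[I_RLO])
    q_tri = valve_flow(p_ra, p_rv, p[I_RRI])
    q_pul = valve_flow(p_rv, p_ap, p[I_RRO] + p[I_RCP])

    q_seg = x[S.QAO]
    q_pa = x[S.QPA]

    q_ub = (p_aa - p_ub) / r_uba
    q_kid = (p_abd - p_kid) / r_kida
    q_sp = (p_abd - p_sp) / r_spa
    q_ll = (p_abd - p_ll) / r_lla
    q_rl = (p_abd - p_rl) / r_rla

    qv_ub = (p_ub - p_sup) / r_ubv
    qv_kid = (p_kid - p_infe) / r_kidv
    qv_sp = (p_sp - p_infe) / r_spv
    # the muscle pump squeezes the deep leg veins: the intramuscular
    # pressure drives the venous outflow, rectified by the venous valves
    qv_ll = valve_flow(p_ll + pim_ll, p_infe, r_llv)
    qv_rl = valve_flow(p_rl + pim_rl, p_infe, r_rlv)

    q_sup = (p_sup - p_ra) / p[I_RSUP]
    q_ive = starling_resistor_flow(p_infe, p_infi, pintr, p[I_RINFEXT])
    q_ivi = (p_infi - p_ra) / p[I_RINFINT]
    q_vp = (p_vp - p_la) / p[I_RVP]

    # --- derivatives -----------------------------------------------------
    dx[S.VLA] = q_vp - q_mit
    dx[S.VLV] = q_mit - q_av
    dx[S.VRA] = q_sup + q_ivi - q_tri
    dx[S.VRV] = q_tri - q_pul
    dx[S.VAA] = q_av - q_seg - q_ub
    dx[S.VABD] = q_seg - q_kid - q_sp - q_ll - q_rl
    dx[S.VUB] = q_ub - qv_ub
    dx[S.VKID] = q_kid - qv_kid
    dx[S.VSP] = q_sp - qv_sp
    dx[S.VLL] = q_ll - qv_ll
    dx[S.VRL] = q_rl - qv_rl
    dx[S.VSUP] = qv_ub - q_sup
    dx[S.VINFE] = qv_kid + qv_sp + qv_ll + qv_rl - q_ive
    dx[S.VINFI] = q_ive - q_ivi
    dx[S.VAP] = q_pul - q_pa
    dx[S.VVP] = q_pa - q_vp

    dx[S.QAO] = (p_aa - p_abd - (p[I_RAA] + p[I_RABD]) * q_seg) \
        / (p[I_LAA] + p[I_LABD])
    dx[S.QPA] = (p_ap - p_vp - p[I_RAP] * q_pa) / p[I_LAP]

    dx[S.TCPH] = 1.0

    return (q_av, q_ub, q_kid, q_sp, q_ll, q_rl,
            qv_ub, qv_kid, qv_sp, qv_ll, qv_rl, q_pa, paa_trans, p_ra, p_aa)
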