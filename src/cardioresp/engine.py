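"""Closed-loop integration of the full cardiorespiratory model.

One fixed-step RK4 integrator advances a single flat state vector holding
the circulation, lung mechanics, alveolar and tissue gas stores, the
baroreflex afferent filter, and every first-order controller block (see
:mod:`cardioresp.state`).  Discrete events are handled between steps:

* cardiac-cycle boundaries — the controlled heart period is latched for the
  whole next cycle and per-cycle means are emitted;
* breath boundaries — the ventilation controller reads the breath-averaged
  upper-body arterial gas tensions and retunes tidal volume and frequency;
* efferent delays — sympathetic and vagal activities travel through pure
  delay lines (ring buffers) before reaching the effector static responses.

Within a step the delayed efferent activities (hence the effector static
responses) are frozen; everything else, including the metabolic static
functions and the sympatholysis gate, is evaluated inside the right-hand
side at every RK4 sub-stage.  Two runs with identical inputs are
bit-identical: there is no randomness anywhere in the model.

The default step of 0.25 ms resolves the fastest network element (the
pulmonary inertance branch, ~0.2 ms time constant in the heart-failure
parameterisation) with a comfortable stability margin; halving it changes
steady-state stage summaries by well under 1%.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._compat import maybe_jit
from . import state as S
from .config import (
    ConditionProfile, NumericalSettings, load_profile,
    I_HR_SET, I_CLA, I_CRA, I_VLV0, I_VRV0, I_ELMAX, I_ERMAX,
    I_AL, I_BL, I_CL, I_AR, I_BR, I_CR,
    I_CAA, I_CABD, I_CUB, I_CKID, I_CSP, I_CLL, I_CRL,
    I_CSUP, I_CINFEXT, I_CINFINT, I_CAP, I_CVP, I_VAP0, I_VVP0,
    I_RUBA_SET, I_RKIDA_SET, I_RSPA_SET, I_RLLA_SET, I_RRLA_SET,
    I_RUBV_SET, I_RKIDV_SET, I_RSPV_SET, I_RLLV_SET, I_RRLV_SET,
    I_VUB0_SET, I_VKID0_SET, I_VSP0_SET, I_VLL0_SET, I_VRL0_SET,
    I_WEIGHT, I_BLOOD_PER_KG,
    I_K_DV, I_P_CO2TR, I_E_LUNG, I_P_CO2I, I_PIMMAX, I_PPL0, I_P_O2I,
    I_PS, I_R_AW, I_ALPHA, I_BETA, I_GAMMA, I_DELTA, I_EPS, I_V_EEXP,
    I_A, I_B, I_C, I_D, I_KA, I_KES, I_KEV, I_FES0, I_FES_INF,
    I_FEV0, I_FEV_INF0, I_PAA_SET0, I_TAU_P, I_TAU_Z,
    I_FAS_MIN, I_FAS_MAX, I_D_HS, I_D_HV,
    I_C_TCS, I_C_TCV, I_C_ELMAXS, I_C_ERMAXS,
    I_C_RUBAS, I_C_RKIDAS, I_C_RSPAS, I_C_RLLAS, I_C_RRLAS,
    I_C_VUB0S, I_C_VKID0S, I_C_VSP0S, I_C_VLL0S, I_C_VRL0S,
    I_C_RUBAMET, I_C_RKIDAMET, I_C_RSPAMET, I_C_RLLAMET, I_C_RRLAMET,
    I_C_RUBVMET, I_C_RKIDVMET, I_C_RSPVMET, I_C_RLLVMET, I_C_RRLVMET,
    I_C_O2UBVREF, I_C_O2KIDVREF, I_C_O2SPVREF, I_C_O2LLVREF, I_C_O2RLVREF,
    I_K_MET, I_S0, I_T_MET, I_T_ELMAX, I_T_ERMAX, I_T_RIS,
    I_T_TCS, I_T_TCV, I_T_VIS,
)
from . import hemodynamics as H
from . import respiratory as RESP
from . import ventilation as VC
from . import gas as G
from . import metabolic as MET
from . import baroreflex as B
from .protocol import (WorkloadSchedule, MetabolicDrive, oxygen_uptake,
                       rest_protocol, schedule_state)

__all__ = ["SimulationRecord", "StageSummary", "simulate",
           "steady_state_summary", "export", "initial_state"]

# ---- stage-constant block (K) -------------------------------------------
K_WL = 0
K_VO2 = 1            # 1..5 per-district VO2, ml/min
K_RQ = 6
K_FES_SET = 7
K_FEV_SET = 8
K_FAS0 = 9           # central afferent firing
K_PPL0G = 10         # gauge mean pleural pressure
K_PAA_SET = 11       # workload-reset pressure set point
K_TC_SET = 12
NK = 13

# ---- auxiliary scalar block ---------------------------------------------
A_TC = 0             # latched heart period
A_TV = 1
A_FREQ = 2
A_VL_ANCHOR = 3      # lung volume at breath start (alveolar-volume anchor)
A_T = 4              # absolute time
A_VENT = 5
A_SUM_O2 = 6         # breath accumulators: arterial contents
A_SUM_CO2 = 7
A_NB = 8
A_NCYC = 9           # steps accumulated in current cycle
A_FAS = 10
A_FES = 11
A_FEV = 12
A_PO2ART = 13        # latest breath-mean arterial tensions
A_PCO2ART = 14
NAUX = 15

# ---- per-cycle output channels ------------------------------------------
CYC_COLS = ["t", "map", "paa_trans", "rap", "co", "q_ub", "q_kid", "q_sp",
            "q_ll", "q_rl", "c_art_o2", "c_ven_o2", "c_art_co2", "c_ven_co2",
            "c_llv_o2", "pintr", "elmax", "rlla", "v_total", "fas", "fes",
            "fev", "tc", "vent", "v_sp", "po2alv", "pco2alv", "q_pa", "wl"]
NC = len(CYC_COLS) - 2   # accumulated channels (t, wl added at emission)

BREATH_COLS = ["t", "po2art", "pco2art", "vent", "freq", "tv", "wl"]
TS_COLS = ["t", "wl", "p_aa", "p_lv", "p_la", "p_ra", "q_av", "q_ll",
           "v_lungs", "pintr", "po2alv", "pco2alv", "c_art_o2", "c_ven_o2",
           "vent", "tc", "v_total"]

_NCH = 14  # autonomic effector channels, state order DTCS..DVRL0


@maybe_jit
def _rhs(t_abs, x, dx, p, K, sym_sf, tc_latch, tv, freq, vl_anchor):
    """Full coupled right-hand side; returns the observable tuple."""
    wl = K[K_WL]

    # --- respiration -----------------------------------------------------
    t_b = x[S.TBPH]
    ppl = RESP.pleural_pressure(t_b, tv, freq, p[I_E_LUNG], K[K_PPL0G],
                                p[I_R_AW])
    pintr = RESP.intrathoracic_pressure(ppl)
    dvl = RESP.lung_volume_derivative(ppl, x[S.VLUNGS], p[I_R_AW], p[I_E_LUNG])
    dx[S.VLUNGS] = dvl
    dx[S.TBPH] = 1.0

    # --- muscle pump ------------------------------------------------------
    pim_ll, pim_rl = H.muscle_pump_pressure(t_abs, wl, p[I_PIMMAX])

    # --- effective controlled parameters ---------------------------------
    elmax = p[I_ELMAX] + x[S.DELMAX]
    ermax = p[I_ERMAX] + x[S.DERMAX]

    sf_ub = MET.metabolic_static_function(x[S.CO2V0 + 0], p[I_C_O2UBVREF], p[I_K_MET])
    sf_kid = MET.metabolic_static_function(x[S.CO2V0 + 1], p[I_C_O2KIDVREF], p[I_K_MET])
    sf_sp = MET.metabolic_static_function(x[S.CO2V0 + 2], p[I_C_O2SPVREF], p[I_K_MET])
    sf_ll = MET.metabolic_static_function(x[S.CO2V0 + 3], p[I_C_O2LLVREF], p[I_K_MET])
    sf_rl = MET.metabolic_static_function(x[S.CO2V0 + 4], p[I_C_O2RLVREF], p[I_K_MET])

    s0 = p[I_S0]
    r_uba = MET.arterial_resistance_combined(p[I_RUBA_SET], s0, x[S.DRAS0 + 0], sf_ub, x[S.DRAMET0 + 0])
    r_kida = MET.arterial_resistance_combined(p[I_RKIDA_SET], s0, x[S.DRAS0 + 1], sf_kid, x[S.DRAMET0 + 1])
    r_spa = MET.arterial_resistance_combined(p[I_RSPA_SET], s0, x[S.DRAS0 + 2], sf_sp, x[S.DRAMET0 + 2])
    r_lla = MET.arterial_resistance_combined(p[I_RLLA_SET], s0, x[S.DRAS0 + 3], sf_ll, x[S.DRAMET0 + 3])
    r_rla = MET.arterial_resistance_combined(p[I_RRLA_SET], s0, x[S.DRAS0 + 4], sf_rl, x[S.DRAMET0 + 4])

    r_ubv = MET.venous_resistance(p[I_RUBV_SET], x[S.DRVMET0 + 0])
    r_kidv = MET.venous_resistance(p[I_RKIDV_SET], x[S.DRVMET0 + 1])
    r_spv = MET.venous_resistance(p[I_RSPV_SET], x[S.DRVMET0 + 2])
    r_llv = MET.venous_resistance(p[I_RLLV_SET], x[S.DRVMET0 + 3])
    r_rlv = MET.venous_resistance(p[I_RRLV_SET], x[S.DRVMET0 + 4])

    vub0 = p[I_VUB0_SET] + x[S.DV00 + 0]
    vkid0 = p[I_VKID0_SET] + x[S.DV00 + 1]
    vsp0 = p[I_VSP0_SET] + x[S.DV00 + 2]
    vll0 = p[I_VLL0_SET] + x[S.DV00 + 3]
    vrl0 = p[I_VRL0_SET] + x[S.DV00 + 4]

    # --- circulation ------------------------------------------------------
    (q_av, q_ub, q_kid, q_sp, q_ll, q_rl,
     qv_ub, qv_kid, qv_sp, qv_ll, qv_rl,
     q_pa, paa_trans, p_ra, p_aa) = H.circulation_derivatives(
        x, dx, p, elmax, ermax, tc_latch,
        r_uba, r_kida, r_spa, r_lla, r_rla,
        r_ubv, r_kidv, r_spv, r_llv, r_rlv,
        vub0, vkid0, vsp0, vll0, vrl0,
        pintr, pim_ll, pim_rl)

    # --- gas transport ----------------------------------------------------
    w_ub = max(qv_ub, 0.0)
    w_kid = max(qv_kid, 0.0)
    w_sp = max(qv_sp, 0.0)
    w_ll = max(qv_ll, 0.0)
    w_rl = max(qv_rl, 0.0)
    wsum = w_ub + w_kid + w_sp + w_ll + w_rl
    if wsum > 1.0e-9:
        cv_o2 = (w_ub * x[S.CO2V0] + w_kid * x[S.CO2V0 + 1]
                 + w_sp * x[S.CO2V0 + 2] + w_ll * x[S.CO2V0 + 3]
                 + w_rl * x[S.CO2V0 + 4]) / wsum
        cv_co2 = (w_ub * x[S.CCO2V0] + w_kid * x[S.CCO2V0 + 1]
                  + w_sp * x[S.CCO2V0 + 2] + w_ll * x[S.CCO2V0 + 3]
                  + w_rl * x[S.CCO2V0 + 4]) / wsum
    else:
        cv_o2 = 0.2 * (x[S.CO2V0] + x[S.CO2V0 + 1] + x[S.CO2V0 + 2]
                       + x[S.CO2V0 + 3] + x[S.CO2V0 + 4])
        cv_co2 = 0.2 * (x[S.CCO2V0] + x[S.CCO2V0 + 1] + x[S.CCO2V0 + 2]
                        + x[S.CCO2V0 + 3] + x[S.CCO2V0 + 4])

    ps = p[I_PS]
    c_art_o2 = G.arterial_mixing(G.o2_content(x[S.PO2ALV]), cv_o2, ps)
    c_art_co2 = G.arterial_mixing(G.co2_content(x[S.PCO2ALV]), cv_co2, ps)

    vdot_signed = p[I_K_DV] * dvl
    inspiration = vdot_signed > 0.0
    # alveolar gas volume: end-expiratory volume plus the effective part of
    # the breath excursion above the breath-start (end-expiratory) anchor
    v_alv = p[I_V_EEXP] + p[I_K_DV] * max(x[S.VLUNGS] - vl_anchor, 0.0)
    d_o2, d_co2 = G.alveolar_derivatives(
        x[S.PO2ALV], x[S.PCO2ALV], v_alv, x[S.VAP], q_pa,
        cv_o2, cv_co2, max(vdot_signed, 0.0), inspiration,
        p[I_P_O2I], p[I_P_CO2I], ps)
    dx[S.PO2ALV] = d_o2
    dx[S.PCO2ALV] = d_co2

    rq = K[K_RQ]
    d, dc = G.tissue_derivatives(x[S.CO2V0], x[S.CCO2V0], c_art_o2, c_art_co2,
                                 q_ub, max(x[S.VUB], 1.0), K[K_VO2], rq)
    dx[S.CO2V0], dx[S.CCO2V0] = d, dc
    d, dc = G.tissue_derivatives(x[S.CO2V0 + 1], x[S.CCO2V0 + 1], c_art_o2,
                                 c_art_co2, q_kid, max(x[S.VKID], 1.0),
                                 K[K_VO2 + 1], rq)
    dx[S.CO2V0 + 1], dx[S.CCO2V0 + 1] = d, dc
    d, dc = G.tissue_derivatives(x[S.CO2V0 + 2], x[S.CCO2V0 + 2], c_art_o2,
                                 c_art_co2, q_sp, max(x[S.VSP], 1.0),
                                 K[K_VO2 + 2], rq)
    dx[S.CO2V0 + 2], dx[S.CCO2V0 + 2] = d, dc
    d, dc = G.tissue_derivatives(x[S.CO2V0 + 3], x[S.CCO2V0 + 3], c_art_o2,
                                 c_art_co2, q_ll, max(x[S.VLL], 1.0),
                                 K[K_VO2 + 3], rq)
    dx[S.CO2V0 + 3], dx[S.CCO2V0 + 3] = d, dc
    d, dc = G.tissue_derivatives(x[S.CO2V0 + 4], x[S.CCO2V0 + 4], c_art_o2,
                                 c_art_co2, q_rl, max(x[S.VRL], 1.0),
                                 K[K_VO2 + 4], rq)
    dx[S.CO2V0 + 4], dx[S.CCO2V0 + 4] = d, dc

    # --- baroreflex afferent filter --------------------------------------
    dpaa = dx[S.VAA] / p[I_CAA]
    dx[S.PFILT] = B.afferent_filter_derivative(paa_trans, dpaa, x[S.PFILT],
                                               p[I_TAU_P], p[I_TAU_Z])

    # --- controller first-order blocks (static responses frozen) ---------
    dx[S.DTCS] = (sym_sf[0] - x[S.DTCS]) / p[I_T_TCS]
    dx[S.DTCV] = (sym_sf[1] - x[S.DTCV]) / p[I_T_TCV]
    dx[S.DELMAX] = (sym_sf[2] - x[S.DELMAX]) / p[I_T_ELMAX]
    dx[S.DERMAX] = (sym_sf[3] - x[S.DERMAX]) / p[I_T_ERMAX]
    for i in range(5):
        dx[S.DRAS0 + i] = (sym_sf[4 + i] - x[S.DRAS0 + i]) / p[I_T_RIS]
        dx[S.DV00 + i] = (sym_sf[9 + i] - x[S.DV00 + i]) / p[I_T_VIS]

    dx[S.DRAMET0 + 0] = MET.metabolic_dynamics_derivative(sf_ub, x[S.DRAMET0 + 0], p[I_C_RUBAMET], p[I_T_MET])
    dx[S.DRAMET0 + 1] = MET.metabolic_dynamics_derivative(sf_kid, x[S.DRAMET0 + 1], p[I_C_RKIDAMET], p[I_T_MET])
    dx[S.DRAMET0 + 2] = MET.metabolic_dynamics_derivative(sf_sp, x[S.DRAMET0 + 2], p[I_C_RSPAMET], p[I_T_MET])
    dx[S.DRAMET0 + 3] = MET.metabolic_dynamics_derivative(sf_ll, x[S.DRAMET0 + 3], p[I_C_RLLAMET], p[I_T_MET])
    dx[S.DRAMET0 + 4] = MET.metabolic_dynamics_derivative(sf_rl, x[S.DRAMET0 + 4], p[I_C_RRLAMET], p[I_T_MET])
    dx[S.DRVMET0 + 0] = MET.metabolic_dynamics_derivative(sf_ub, x[S.DRVMET0 + 0], p[I_C_RUBVMET], p[I_T_MET])
    dx[S.DRVMET0 + 1] = MET.metabolic_dynamics_derivative(sf_kid, x[S.DRVMET0 + 1], p[I_C_RKIDVMET], p[I_T_MET])
    dx[S.DRVMET0 + 2] = MET.metabolic_dynamics_derivative(sf_sp, x[S.DRVMET0 + 2], p[I_C_RSPVMET], p[I_T_MET])
    dx[S.DRVMET0 + 3] = MET.metabolic_dynamics_derivative(sf_ll, x[S.DRVMET0 + 3], p[I_C_RLLVMET], p[I_T_MET])
    dx[S.DRVMET0 + 4] = MET.metabolic_dynamics_derivative(sf_rl, x[S.DRVMET0 + 4], p[I_C_RRLVMET], p[I_T_MET])

    return (q_av, q_ub, q_kid, q_sp, q_ll, q_rl, q_pa, paa_trans, p_aa,
            p_ra, c_art_o2, c_art_co2, cv_o2, cv_co2, pintr,
            r_lla, elmax)


@maybe_jit
def _run_chunk(x, p, K, aux, fes_buf, fev_buf, cnt, n_steps, dt, dec,
               csum, cyc_out, breath_out, ts_out):
    """Advance ``n_steps`` fixed RK4 steps with event handling.

    ``cnt`` holds [cycle rows, breath rows, ts rows, global step] counters.
    Returns 0 on success, 1 if the state went non-finite.
    """
    nb_s = fes_buf.shape[0]
    nb_v = fev_buf.shape[0]
    dx1 = np.empty(S.NX)
    dx2 = np.empty(S.NX)
    dx3 = np.empty(S.NX)
    dx4 = np.empty(S.NX)
    xt = np.empty(S.NX)
    sym_sf = np.empty(_NCH)
    wl = K[K_WL]

    for _ in range(n_steps):
        gstep = cnt[3]

        # delayed efferent activities -> frozen static responses
        fes_d = fes_buf[gstep % nb_s]
        fev_d = fev_buf[gstep % nb_v]
        base = B.effector_static_sympathetic(fes_d, K[K_FES_SET],
                                             p[I_FES_INF], 1.0)
        sym_sf[0] = p[I_C_TCS] * base
        sym_sf[1] = B.effector_static_vagal(fev_d, K[K_FEV_SET], p[I_C_TCV])
        sym_sf[2] = p[I_C_ELMAXS] * base
        sym_sf[3] = p[I_C_ERMAXS] * base
        sym_sf[4] = p[I_C_RUBAS] * base
        sym_sf[5] = p[I_C_RKIDAS] * base
        sym_sf[6] = p[I_C_RSPAS] * base
        sym_sf[7] = p[I_C_RLLAS] * base
        sym_sf[8] = p[I_C_RRLAS] * base
        sym_sf[9] = p[I_C_VUB0S] * base
        sym_sf[10] = p[I_C_VKID0S] * base
        sym_sf[11] = p[I_C_VSP0S] * base
        sym_sf[12] = p[I_C_VLL0S] * base
        sym_sf[13] = p[I_C_VRL0S] * base

        t0 = aux[A_T]
        tc_l = aux[A_TC]
        tv = aux[A_TV]
        freq = aux[A_FREQ]
        anchor = aux[A_VL_ANCHOR]

        # RK4 (observables taken at the accepted pre-step state)
        obs = _rhs(t0, x, dx1, p, K, sym_sf, tc_l, tv, freq, anchor)
        for i in range(S.NX):
            xt[i] = x[i] + 0.5 * dt * dx1[i]
        _rhs(t0 + 0.5 * dt, xt, dx2, p, K, sym_sf, tc_l, tv, freq, anchor)
        for i in range(S.NX):
            xt[i] = x[i] + 0.5 * dt * dx2[i]
        _rhs(t0 + 0.5 * dt, xt, dx3, p, K, sym_sf, tc_l, tv, freq, anchor)
        for i in range(S.NX):
            xt[i] = x[i] + dt * dx3[i]
        _rhs(t0 + dt, xt, dx4, p, K, sym_sf, tc_l, tv, freq, anchor)
        for i in range(S.NX):
            x[i] += dt / 6.0 * (dx1[i] + 2.0 * dx2[i] + 2.0 * dx3[i] + dx4[i])

        (q_av, q_ub, q_kid, q_sp, q_ll, q_rl, q_pa, paa_trans, p_aa, p_ra,
         c_art_o2, c_art_co2, cv_o2, cv_co2, pintr, r_lla, elmax) = obs

        v_total = 0.0
        for i in range(16):
            v_total += x[i]

        # per-cycle accumulation
        csum[0] += p_aa
        csum[1] += paa_trans
        csum[2] += p_ra
        csum[3] += q_av
        csum[4] += q_ub
        csum[5] += q_kid
        csum[6] += q_sp
        csum[7] += q_ll
        csum[8] += q_rl
        csum[9] += c_art_o2
        csum[10] += cv_o2
        csum[11] += c_art_co2
        csum[12] += cv_co2
        csum[13] += x[S.CO2V0 + 3]
        csum[14] += pintr
        csum[15] += elmax
        csum[16] += r_lla
        csum[17] += v_total
        csum[18] += aux[A_FAS]
        csum[19] += aux[A_FES]
        csum[20] += aux[A_FEV]
        csum[21] += aux[A_TC]
        csum[22] += aux[A_VENT]
        csum[23] += x[S.VSP]
        csum[24] += x[S.PO2ALV]
        csum[25] += x[S.PCO2ALV]
        csum[26] += q_pa
        aux[A_NCYC] += 1.0

        # breath accumulation (arterial contents, inverted at breath end)
        aux[A_SUM_O2] += c_art_o2
        aux[A_SUM_CO2] += c_art_co2
        aux[A_NB] += 1.0

        aux[A_T] = t0 + dt
        cnt[3] = gstep + 1

        # efferent activities from the (new) filtered pressure -> delay lines
        fas = B.afferent_firing(x[S.PFILT], K[K_PAA_SET], p[I_KA],
                                p[I_FAS_MIN], p[I_FAS_MAX])
        fes = B.sympathetic_activity(fas, wl, p[I_FES0], p[I_FES_INF],
                                     p[I_KES], p[I_B])
        fev = B.vagal_activity(fas, wl, p[I_FEV0], p[I_FEV_INF0],
                               p[I_KEV], K[K_FAS0], p[I_C], p[I_D])
        aux[A_FAS] = fas
        aux[A_FES] = fes
        aux[A_FEV] = fev
        fes_buf[cnt[3] % nb_s] = fes
        fev_buf[cnt[3] % nb_v] = fev

        # decimated time series
        if gstep % dec == 0 and cnt[2] < ts_out.shape[0]:
            it = cnt[2]
            p_lv = H.ventricular_pressure(x[S.VLV], x[S.TCPH], aux[A_TC],
                                          p[I_ELMAX] + x[S.DELMAX], p[I_VLV0],
                                          p[I_AL], p[I_BL], p[I_CL], pintr)
            p_la = H.atrial_pressure(x[S.VLA], p[I_CLA], 0.0, pintr)
            ts_out[it, 0] = aux[A_T]
            ts_out[it, 1] = wl
            ts_out[it, 2] = p_aa
            ts_out[it, 3] = p_lv
            ts_out[it, 4] = p_la
            ts_out[it, 5] = p_ra
            ts_out[it, 6] = q_av
            ts_out[it, 7] = q_ll
            ts_out[it, 8] = x[S.VLUNGS]
            ts_out[it, 9] = pintr
            ts_out[it, 10] = x[S.PO2ALV]
            ts_out[it, 11] = x[S.PCO2ALV]
            ts_out[it, 12] = c_art_o2
            ts_out[it, 13] = cv_o2
            ts_out[it, 14] = aux[A_VENT]
            ts_out[it, 15] = aux[A_TC]
            ts_out[it, 16] = v_total
            cnt[2] = it + 1

        # cardiac cycle boundary: emit means, latch the controlled period
        if x[S.TCPH] >= aux[A_TC]:
            n = aux[A_NCYC]
            if cnt[0] < cyc_out.shape[0] and n > 0:
                ic = cnt[0]
                cyc_out[ic, 0] = aux[A_T]
                for j in range(NC):
                    cyc_out[ic, 1 + j] = csum[j] / n
                cyc_out[ic, 1 + NC] = wl
                cnt[0] = ic + 1
            for j in range(NC):
                csum[j] = 0.0
            aux[A_NCYC] = 0.0
            x[S.TCPH] -= aux[A_TC]
            tc_new = K[K_TC_SET] + x[S.DTCS] + x[S.DTCV]
            if tc_new < 0.25:
                tc_new = 0.25
            elif tc_new > 3.0:
                tc_new = 3.0
            aux[A_TC] = tc_new
            if not (math.isfinite(x[S.VLV]) and math.isfinite(p_aa)
                    and math.isfinite(x[S.PO2ALV])):
                return 1

        # breath boundary: retune the ventilation controller
        tb_period = 60.0 / aux[A_FREQ]
        if x[S.TBPH] >= tb_period:
            x[S.TBPH] -= tb_period
            nb = aux[A_NB]
            if nb > 0:
                po2 = G._o2_pp_core(aux[A_SUM_O2] / nb)
                pco2 = G._co2_pp_core(aux[A_SUM_CO2] / nb)
                aux[A_PO2ART] = po2
                aux[A_PCO2ART] = pco2
                vent = VC.minute_ventilation(po2, pco2, p[I_ALPHA], p[I_BETA],
                                             p[I_GAMMA], p[I_P_CO2TR])
                freq_n, tv_n = VC.breathing_pattern(vent, p[I_DELTA], p[I_EPS])
                aux[A_VENT] = vent
                aux[A_FREQ] = freq_n
                aux[A_TV] = tv_n
            aux[A_VL_ANCHOR] = x[S.VLUNGS]
            if cnt[1] < breath_out.shape[0]:
                ibr = cnt[1]
                breath_out[ibr, 0] = aux[A_T]
                breath_out[ibr, 1] = aux[A_PO2ART]
                breath_out[ibr, 2] = aux[A_PCO2ART]
                breath_out[ibr, 3] = aux[A_VENT]
                breath_out[ibr, 4] = aux[A_FREQ]
                breath_out[ibr, 5] = aux[A_TV]
                breath_out[ibr, 6] = wl
                cnt[1] = ibr + 1
            aux[A_SUM_O2] = 0.0
            aux[A_SUM_CO2] = 0.0
            aux[A_NB] = 0.0

    return 0


# --------------------------------------------------------------------------
# Python-side orchestration
# --------------------------------------------------------------------------
@dataclasses.dataclass
class SimulationRecord:
    """Time series plus per-cycle and per-breath tables of one simulation."""

    time_series: pd.DataFrame
    cycles: pd.DataFrame
    breaths: pd.DataFrame
    profile: ConditionProfile
    schedule: WorkloadSchedule
    numerics: NumericalSettings
    stage_workloads: tuple[float, ...]


@dataclasses.dataclass
class StageSummary:
    """Steady-state summary of one workload stage (15-cycle means)."""

    wl: float
    hr: float                 # bpm
    map: float                # mmHg
    rap: float                # mmHg
    co: float                 # l/min
    q_leg: float              # single (left) leg flow, l/min
    tpr: float                # mmHg/(cm3/s)
    r_leg: float              # effective left-leg arterial resistance
    avdiff_central: float     # ml/dl
    avdiff_leg: float         # ml/dl
    vent: float               # l/min
    q_rest_regions: float     # l/min
    r_rest_regions: float     # mmHg/(cm3/s), lumped
    v_splanchnic: float       # cm3
    elmax: float              # mmHg/cm3
    po2alv: float             # mmHg
    pco2alv: float            # mmHg
    vo2_fick: float           # CO x central a-v diff, ml/min
    v_total: float            # cm3
    converged: bool

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["converged"] = bool(d["converged"])
        return d


def initial_state(profile: ConditionProfile) -> tuple[np.ndarray, np.ndarray]:
    """Build the initial state vector and auxiliary block for a profile.

    Compartments start at plausible resting pressures with the total blood
    volume set from body weight (70 ml/kg); the balance of the budget is
    assigned to the splanchnic reservoir.  Gas stores start at arterial
    norms and the district reference venous contents; all controller
    deviations start at zero, so the closed loop settles into its own
    operating point within the first stage.
    """
    p = profile.to_array()
    x = np.zeros(S.NX)

    # chambers (transmural pressure targets)
    x[S.VLA] = p[I_CLA] * 8.0
    x[S.VRA] = p[I_CRA] * 6.0
    x[S.VLV] = p[I_VLV0] + 110.0
    x[S.VRV] = p[I_VRV0] + 110.0
    # vessels
    x[S.VAA] = p[I_CAA] * 90.0
    x[S.VABD] = p[I_CABD] * 90.0
    x[S.VUB] = p[I_VUB0_SET] + p[I_CUB] * 10.0
    x[S.VKID] = p[I_VKID0_SET] + p[I_CKID] * 10.0
    x[S.VSP] = p[I_VSP0_SET] + p[I_CSP] * 10.0
    x[S.VLL] = p[I_VLL0_SET] + p[I_CLL] * 10.0
    x[S.VRL] = p[I_VRL0_SET] + p[I_CRL] * 10.0
    x[S.VSUP] = p[I_CSUP] * 6.0
    x[S.VINFE] = p[I_CINFEXT] * 6.0
    x[S.VINFI] = p[I_CINFINT] * 6.0
    x[S.VAP] = p[I_VAP0] + p[I_CAP] * 16.0
    x[S.VVP] = p[I_VVP0] + p[I_CVP] * 10.0
    # close the blood-volume budget through the splanchnic reservoir
    target = p[I_BLOOD_PER_KG] * p[I_WEIGHT]
    x[S.VSP] += target - x[:16].sum()

    x[S.QAO] = 80.0
    x[S.QPA] = 80.0
    x[S.VLUNGS] = -_ppl0_gauge(p) / p[I_E_LUNG]

    x[S.PO2ALV] = 100.0
    x[S.PCO2ALV] = 40.0
    refs = (p[I_C_O2UBVREF], p[I_C_O2KIDVREF], p[I_C_O2SPVREF],
            p[I_C_O2LLVREF], p[I_C_O2RLVREF])
    for i in range(5):
        x[S.CO2V0 + i] = refs[i]
        x[S.CCO2V0 + i] = G.co2_content(46.0)
    x[S.PFILT] = p[I_PAA_SET0]

    aux = np.zeros(NAUX)
    aux[A_TC] = 60.0 / p[I_HR_SET]
    vent0 = VC.minute_ventilation(95.0, 40.0, p[I_ALPHA], p[I_BETA],
                                  p[I_GAMMA], p[I_P_CO2TR])
    freq0, tv0 = VC.breathing_pattern(vent0, p[I_DELTA], p[I_EPS])
    aux[A_VENT] = vent0
    aux[A_FREQ] = freq0
    aux[A_TV] = tv0
    aux[A_VL_ANCHOR] = x[S.VLUNGS]
    aux[A_PO2ART] = 95.0
    aux[A_PCO2ART] = 40.0
    return x, aux


def _ppl0_gauge(p: np.ndarray) -> float:
    # Table value is absolute (mmHg); the engine works in gauge pressures.
    return p[I_PPL0] - 760.0


def _stage_constants(profile: ConditionProfile, p: np.ndarray,
                     wl: float) -> np.ndarray:
    drive = oxygen_uptake(wl, profile)
    fes_set, fev_set = B.rest_set_activities(profile)
    K = np.zeros(NK)
    K[K_WL] = wl
    K[K_VO2:K_VO2 + 5] = drive.as_tuple()
    K[K_RQ] = drive.rq
    K[K_FES_SET] = fes_set
    K[K_FEV_SET] = fev_set
    K[K_FAS0] = B.central_fas(profile)
    K[K_PPL0G] = _ppl0_gauge(p)
    K[K_PAA_SET] = B.set_point_pressure(wl, profile.Paa_set0, profile.A)
    K[K_TC_SET] = 60.0 / profile.HR_set
    return K


def simulate(profile: ConditionProfile,
             schedule: WorkloadSchedule | None = None,
             numerics: NumericalSettings | None = None) -> SimulationRecord:
    """Run the closed loop over a workload schedule; fully deterministic."""
    if schedule is None:
        schedule = rest_protocol()
    if numerics is None:
        numerics = NumericalSettings()
    p = profile.to_array()
    dt = numerics.dt
    dec = numerics.decimation

    x, aux = initial_state(profile)
    lag_s = max(1, int(round(profile.D_Hs / dt)))
    lag_v = max(1, int(round(profile.D_Hv / dt)))
    fes_set, fev_set = B.rest_set_activities(profile)
    fes_buf = np.full(lag_s, fes_set)
    fev_buf = np.full(lag_v, fev_set)
    cnt = np.zeros(4, dtype=np.int64)
    csum = np.zeros(NC)

    starts = [t for t, _ in schedule.steps]
    wls = [w for _, w in schedule.steps]
    durations = [t2 - t1 for t1, t2 in zip(starts, starts[1:])]
    durations.append(numerics.stage_duration)

    cyc_rows, breath_rows, ts_rows = [], [], []
    stage_wls = []
    for wl, dur in zip(wls, durations):
        n_steps = int(round(dur / dt))
        if n_steps <= 0:
            continue
        K = _stage_constants(profile, p, wl)
        cyc_out = np.zeros((int(dur / 0.25) + 16, len(CYC_COLS)))
        breath_out = np.zeros((int(dur / 1.5) + 16, len(BREATH_COLS)))
        ts_out = np.zeros((n_steps // dec + 2, len(TS_COLS)))
        cnt[0] = cnt[1] = cnt[2] = 0
        status = _run_chunk(x, p, K, aux, fes_buf, fev_buf, cnt,
                            n_steps, dt, dec, csum, cyc_out, breath_out,
                            ts_out)
        if status != 0:
            raise FloatingPointError(
                f"simulation diverged (non-finite state) at WL={wl} W, "
                f"t≈{aux[A_T]:.2f} s")
        cyc_rows.append(cyc_out[:cnt[0]])
        breath_rows.append(breath_out[:cnt[1]])
        ts_rows.append(ts_out[:cnt[2]])
        stage_wls.append(wl)

    def _stack(rows, cols):
        if not rows:
            return pd.DataFrame(np.empty((0, len(cols))), columns=cols)
        return pd.DataFrame(np.vstack(rows), columns=cols)

    cycles = _stack(cyc_rows, CYC_COLS)
    breaths = _stack(breath_rows, BREATH_COLS)
    ts = _stack(ts_rows, TS_COLS)
    return SimulationRecord(time_series=ts, cycles=cycles, breaths=breaths,
                            profile=profile, schedule=schedule,
                            numerics=numerics,
                            stage_workloads=tuple(stage_wls))


def steady_state_summary(record: SimulationRecord) -> list[StageSummary]:
    """Per-stage steady-state summaries over the final cycles of each stage."""
    ncyc = record.numerics.summary_cycles
    tol = record.numerics.ss_tol
    out: list[StageSummary] = []
    v_sp_rest = None
    for wl in record.stage_workloads:
        stage = record.cycles[record.cycles["wl"] == wl]
        tail = stage.tail(ncyc)
        prev = stage.iloc[:-ncyc].tail(ncyc) if len(stage) > 2 * ncyc else None
        m = tail.mean(numeric_only=True)
        converged = False
        if prev is not None and len(prev) == ncyc:
            pm = prev.mean(numeric_only=True)
            rel_map = abs(m["map"] - pm["map"]) / max(abs(pm["map"]), 1e-9)
            rel_co = abs(m["co"] - pm["co"]) / max(abs(pm["co"]), 1e-9)
            converged = rel_map < tol and rel_co < tol
        co_cm3s = m["co"]
        q_rr = m["q_ub"] + m["q_kid"] + m["q_sp"]
        if v_sp_rest is None:
            v_sp_rest = m["v_sp"]
        out.append(StageSummary(
            wl=wl,
            hr=60.0 / m["tc"],
            map=m["map"],
            rap=m["rap"],
            co=co_cm3s * 0.06,
            q_leg=m["q_ll"] * 0.06,
            tpr=(m["map"] - m["rap"]) / max(co_cm3s, 1e-9),
            r_leg=m["rlla"],
            avdiff_central=m["c_art_o2"] - m["c_ven_o2"],
            avdiff_leg=m["c_art_o2"] - m["c_llv_o2"],
            vent=m["vent"],
            q_rest_regions=q_rr * 0.06,
            r_rest_regions=(m["map"] - m["rap"]) / max(q_rr, 1e-9),
            v_splanchnic=m["v_sp"],
            elmax=m["elmax"],
            po2alv=m["po2alv"],
            pco2alv=m["pco2alv"],
            vo2_fick=co_cm3s * 0.6 * (m["c_art_o2"] - m["c_ven_o2"]),
            v_total=m["v_total"],
            converged=converged,
        ))
    return out


def export(record: SimulationRecord, directory: str | Path,
           summaries: Sequence[StageSummary] | None = None) -> dict[str, Path]:
    """Write the record (CSV) and stage summaries (JSON) to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("time_series", record.time_series),
                     ("cycles", record.cycles),
                     ("breaths", record.breaths)):
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    if summaries is None:
        summaries = steady_state_summary(record)
    spath = directory / "summary.json"
    payload = {
        "condition": record.profile.condition,
        "stages": {f"{s.wl:g}W": s.as_dict() for s in summaries},
        "units": {
            "hr": "bpm", "map": "mmHg", "rap": "mmHg", "co": "l/min",
            "q_leg": "l/min", "tpr": "mmHg/(cm3/s)",
            "r_leg": "mmHg/(cm3/s)", "avdiff_central": "ml/dl",
            "avdiff_leg": "ml/dl", "vent": "l/min",
            "q_rest_regions": "l/min", "r_rest_regions": "mmHg/(cm3/s)",
            "v_splanchnic": "cm3", "elmax": "mmHg/cm3", "vo2_fick": "ml/min",
            "v_total": "cm3",
        },
    }
    spath.write_text(json.dumps(payload, indent=2))
    paths["summary"] = spath
    return paths
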