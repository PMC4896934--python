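"""Baroreflex with exercise resetting.

The transmural ascending-aortic pressure passes through a lead-lag afferent
filter (pole τp, zero τz); the filtered pressure sets the afferent firing
``Fas`` on a logistic curve centred at the workload-shifted set point
``Paa_set = Paa_set0 + A·WL``.  Efferent sympathetic activity falls
exponentially with ``Fas`` and gains an exercise offset ``B·WL``; vagal
activity rises sigmoidally with ``Fas``, its upper limit shrinking with
workload (``D·WL``) on top of a direct withdrawal ``C·WL``, clamped at zero.

Each controlled parameter (heart period, ventricular elastances, district
arterial resistances, district unstressed volumes) has a static response —
logarithmic compression of the delayed sympathetic activity, linear in the
delayed vagal activity — and a first-order dynamic block.  The static
responses vanish at the *rest* operating point (filtered pressure equal to
the rest set point at zero workload), which is where every parameter sits at
its set-point value; exercise resetting then deliberately shifts the
operating values away from rest, producing the workload-driven rise of heart
rate, contractility and vascular tone.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from ._compat import maybe_jit
from .config import ConditionProfile

__all__ = [
    "afferent_filter_derivative", "set_point_pressure", "afferent_firing",
    "sympathetic_activity", "vagal_activity", "central_fas",
    "rest_set_activities", "effector_static_sympathetic",
    "effector_static_vagal", "effector_dynamics_derivative",
    "steady_heart_period", "open_loop_response_curve",
]


@maybe_jit
def afferent_filter_derivative(paa: float, dpaa_dt: float, p_filt: float,
                               tau_p: float, tau_z: float) -> float:
    """Lead-lag afferent filter: τp·dP/dt = Paa + τz·dPaa/dt − P."""
    return (paa + tau_z * dpaa_dt - p_filt) / tau_p


@maybe_jit
def set_point_pressure(wl: float, paa_set0: float, a: float) -> float:
    """Workload-reset arterial pressure set point (mmHg)."""
    return paa_set0 + a * wl


@maybe_jit
def afferent_firing(p_filt: float, paa_set: float, ka: float,
                    fas_min: float, fas_max: float) -> float:
    """Afferent firing (spikes/s), saturating between Fas_min and Fas_max.

    Logistic interpolation ``(Fas_min + Fas_max·e^z)/(1 + e^z)`` with
    ``z = (P − Paa_set)/ka``: the lower and upper saturation levels are
    exactly ``Fas_min`` and ``Fas_max``.
    """
    z = (p_filt - paa_set) / ka
    if z > 50.0:
        sig = 1.0
    elif z < -50.0:
        sig = 0.0
    else:
        e = math.exp(z)
        sig = e / (1.0 + e)
    return fas_min * (1.0 - sig) + fas_max * sig


@maybe_jit
def sympathetic_activity(fas: float, wl: float, fes0: float, fes_inf: float,
                         kes: float, b: float) -> float:
    """Efferent sympathetic activity with the exercise offset B·WL."""
    return fes_inf + (fes0 - fes_inf) * math.exp(-kes * fas) + b * wl


@maybe_jit
def vagal_activity(fas: float, wl: float, fev0: float, fev_inf0: float,
                   kev: float, fas0: float, c: float, d: float) -> float:
    """Efferent vagal activity with exercise withdrawal, clamped at 0.

    Logistic interpolation between ``Fev0`` (low afferent drive) and the
    workload-shrunk upper limit ``Fev∞ = Fev∞0 + D·WL``, plus the direct
    withdrawal ``C·WL``.  At high workload the combination drives Fev to
    zero regardless of pressure — complete vagal withdrawal.
    """
    fev_inf = fev_inf0 + d * wl
    w = (fas - fas0) / kev
    if w > 50.0:
        sig = 1.0
    elif w < -50.0:
        sig = 0.0
    else:
        e = math.exp(w)
        sig = e / (1.0 + e)
    fev = fev0 * (1.0 - sig) + fev_inf * sig + c * wl
    return max(fev, 0.0)


def central_fas(profile: ConditionProfile) -> float:
    """Afferent firing at the central point (filtered pressure = set point)."""
    return 0.5 * (profile.Fas_min + profile.Fas_max)


def rest_set_activities(profile: ConditionProfile) -> tuple[float, float]:
    """(Fes_set, Fev_set): efferent activities at the rest operating point.

    These reference values anchor the static responses: they are evaluated
    once at zero workload with the afferent firing at its central value, so
    that at rest with ``Paa = Paa_set0`` every effector holds its set point,
    while workload resetting moves the operating values away from them.
    """
    fas_c = central_fas(profile)
    fes_set = sympathetic_activity(fas_c, 0.0, profile.Fes0, profile.Fes_inf,
                                   profile.kes, profile.B)
    fev_set = vagal_activity(fas_c, 0.0, profile.Fev0, profile.Fev_inf0,
                             profile.kev, fas_c, profile.C, profile.D)
    return fes_set, fev_set


@maybe_jit
def effector_static_sympathetic(fes_delayed: float, fes_set: float,
                                fes_inf: float, gain: float) -> float:
    """Logarithmic sympathetic static response, zero at ``Fes = Fes_set``.

    ``gain·[ln(Fes_d − Fes_inf + 1) − ln(Fes_set − Fes_inf + 1)]`` — the
    log-compressive family of the source baroreflex model, monotone in the
    delayed activity and exactly zero at the set activity.  Arguments below
    the lower saturation are clamped.
    """
    num = max(fes_delayed - fes_inf + 1.0, 1.0e-9)
    den = max(fes_set - fes_inf + 1.0, 1.0e-9)
    return gain * (math.log(num) - math.log(den))


@maybe_jit
def effector_static_vagal(fev_delayed: float, fev_set: float,
                          gain: float) -> float:
    """Linear vagal static response: gain·(Fev_d − Fev_set)."""
    return gain * (fev_delayed - fev_set)


@maybe_jit
def effector_dynamics_derivative(sf: float, delta_h: float, tau: float) -> float:
    """First-order effector block: dΔH/dt = (sf − ΔH)/T."""
    return (sf - delta_h) / tau


def steady_heart_period(profile: ConditionProfile, p_filt: float, wl: float,
                        sympathetic: bool = True, vagal: bool = True) -> float:
    """Converged heart period (s) for a held filtered pressure and workload.

    At steady state each first-order block settles at its static response,
    so the heart period is ``TC_set + sf_TCs + sf_TCv`` with either channel
    optionally disabled (the open-loop single-channel experiments).
    """
    paa_set = set_point_pressure(wl, profile.Paa_set0, profile.A)
    fas = afferent_firing(p_filt, paa_set, profile.ka,
                          profile.Fas_min, profile.Fas_max)
    fes_set, fev_set = rest_set_activities(profile)
    tc = 60.0 / profile.HR_set
    if sympathetic:
        fes = sympathetic_activity(fas, wl, profile.Fes0, profile.Fes_inf,
                                   profile.kes, profile.B)
        tc += effector_static_sympathetic(fes, fes_set, profile.Fes_inf,
                                          profile.C_TCs)
    if vagal:
        fev = vagal_activity(fas, wl, profile.Fev0, profile.Fev_inf0,
                             profile.kev, central_fas(profile),
                             profile.C, profile.D)
        tc += effector_static_vagal(fev, fev_set, profile.C_TCv)
    return tc


def open_loop_response_curve(profile: ConditionProfile,
                             wl: float,
                             paa_grid: Sequence[float] | np.ndarray,
                             sympathetic: bool = True,
                             vagal: bool = True):
    """Stimulus–response sweep: imposed aortic pressure → steady reflex state.

    For each imposed constant pressure the afferent filter converges to the
    pressure itself (unit DC gain), every delay line and first-order block
    converges to its static value, and the heart rate follows in closed
    form.  Returns a dict of numpy arrays with keys ``paa``, ``fas``,
    ``fes``, ``fev``, ``hr``.
    """
    paa = np.asarray(paa_grid, dtype=float)
    paa_set = set_point_pressure(wl, profile.Paa_set0, profile.A)
    fas = np.array([afferent_firing(p, paa_set, profile.ka, profile.Fas_min,
                                    profile.Fas_max) for p in paa])
    fes = np.array([sympathetic_activity(f, wl, profile.Fes0, profile.Fes_inf,
                                         profile.kes, profile.B) for f in fas])
    fev = np.array([vagal_activity(f, wl, profile.Fev0, profile.Fev_inf0,
                                   profile.kev, central_fas(profile),
                                   profile.C, profile.D) for f in fas])
    hr = np.array([60.0 / steady_heart_period(profile, p, wl,
                                              sympathetic=sympathetic,
                                              vagal=vagal) for p in paa])
    return {"paa": paa, "fas": fas, "fes": fes, "fev": fev, "hr": hr}


def operating_point_hr(profile: ConditionProfile, wl: float,
                       sympathetic: bool = True, vagal: bool = True) -> float:
    """Steady heart rate (bpm) at the reflex operating point for ``wl``.

    The operating point imposes the workload's own set-point pressure, the
    condition highlighted in the open-loop resetting experiments.
    """
    p_op = set_point_pressure(wl, profile.Paa_set0, profile.A)
    return 60.0 / steady_heart_period(profile, p_op, wl,
                                      sympathetic=sympathetic, vagal=vagal)
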