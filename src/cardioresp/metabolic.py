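"""Local metabolic vasodilation and its interaction with sympathetic tone.

Each circulatory district senses its own venous O₂ content through a
sigmoid static function ``sf = 1 − 1/(1 + e^{k·(C_O2iv − C_ref/2)})`` that
sits at ≈1 at the reference content and falls towards 0 as the content drops
to zero.  A first-order block converts the deficit ``C_gain·(sf − 1)`` into
a (negative) resistance deviation for the district's arterial and venous
resistances.

Arterial resistance combines the metabolic and sympathetic drives with
functional sympatholysis: the sympathetic term (set-point non-basal part
plus the baroreflex deviation) is gated by ``sf¹⁰``, so in a hypoxic,
metabolically active district the sympathetic vasoconstriction is abolished
and the resistance collapses towards the basal fraction ``S0`` of its set
point plus the metabolic deviation.
"""
from __future__ import annotations

import math

from ._compat import maybe_jit

__all__ = [
    "metabolic_static_function", "metabolic_dynamics_derivative",
    "venous_resistance", "arterial_resistance_combined", "RESISTANCE_FLOOR",
]

#: Floor on arterial resistance, as a fraction of the basal value Ria_set·S0.
RESISTANCE_FLOOR = 0.05


@maybe_jit
def metabolic_static_function(c_o2iv: float, c_o2iv_ref: float,
                              k_met: float) -> float:
    """Sigmoid metabolic drive in (0, 1), ≈1 at the reference content."""
    z = k_met * (c_o2iv - 0.5 * c_o2iv_ref)
    if z > 50.0:
        return 1.0
    if z < -50.0:
        return 0.0
    return 1.0 - 1.0 / (1.0 + math.exp(z))


@maybe_jit
def metabolic_dynamics_derivative(sf: float, delta_r: float, c_gain: float,
                                  t_met: float) -> float:
    """First-order metabolic block: dΔR/dt = (C·(sf − 1) − ΔR)/T."""
    return (c_gain * (sf - 1.0) - delta_r) / t_met


@maybe_jit
def venous_resistance(riv_set: float, delta_riv_met: float) -> float:
    """Controlled venous resistance, floored at a small positive value."""
    return max(riv_set + delta_riv_met, RESISTANCE_FLOOR * riv_set)


@maybe_jit
def arterial_resistance_combined(ria_set: float, s0: float, delta_ria_s: float,
                                 sf: float, delta_ria_met: float) -> float:
    """Arterial resistance with sympatholysis gating.

    ``Ria = Ria_set·S0 + [Ria_set·(1−S0) + ΔRia_s]·sf¹⁰ + ΔRia_met``,
    floored at a small fraction of the basal resistance ``Ria_set·S0``.
    """
    gate = sf ** 10
    r = ria_set * s0 + (ria_set * (1.0 - s0) + delta_ria_s) * gate \
        + delta_ria_met
    return max(r, RESISTANCE_FLOOR * ria_set * s0)
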