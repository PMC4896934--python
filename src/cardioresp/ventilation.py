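"""Chemoreflex ventilation control.

Minute ventilation responds to the upper-body arterial gas tensions through
an additive hypoxic–hypercapnic drive

    Vent = α·e^{β·P_O2}·(P_CO2 − P_CO2tr) + γ·(P_CO2 − P_CO2tr)

floored at zero below the CO₂ threshold.  Ventilation is then split into
breathing frequency (affine in Vent) and tidal volume (their ratio), and the
tidal volume is reduced to its alveolar-effective part by the dead-space
factor ``K_DV`` (the fraction of each breath reaching the alveoli; its
complement is the Wasserman dead-space/tidal-volume ratio, an affine
function of peak aerobic capacity).
"""
from __future__ import annotations

import math

from ._compat import maybe_jit

__all__ = [
    "minute_ventilation", "breathing_pattern", "effective_tidal_volume",
    "dead_space_fraction",
]


@maybe_jit
def minute_ventilation(p_o2uba: float, p_co2uba: float, alpha: float,
                       beta: float, gamma: float, p_co2tr: float) -> float:
    """Minute ventilation (l/min), floored at 0 below the CO2 threshold."""
    drive = p_co2uba - p_co2tr
    if drive <= 0.0:
        return 0.0
    return alpha * math.exp(beta * p_o2uba) * drive + gamma * drive


@maybe_jit
def breathing_pattern(vent: float, delta: float, eps: float):
    """Split ventilation into (frequency 1/min, tidal volume l)."""
    freq = delta * vent + eps
    tv = vent / freq if vent > 0.0 else 0.0
    return freq, tv


@maybe_jit
def effective_tidal_volume(tv: float, k_dv: float) -> float:
    """Alveolar-effective tidal volume: the fraction ``k_dv`` of each breath."""
    return tv * k_dv


def dead_space_fraction(peak_vo2: float) -> float:
    """Wasserman dead-space/tidal-volume ratio from peak VO2 (ml/min/kg)."""
    if not 0.0 < peak_vo2 <= 50.0:
        raise ValueError(f"peak VO2 {peak_vo2!r} ml/min/kg out of range")
    f = -0.012 * peak_vo2 + 0.611
    return min(max(f, 1.0e-12), 1.0 - 1.0e-12)
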