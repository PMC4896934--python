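"""Ventilation mechanics: pleural pressure waveform and lung volume.

The pleural pressure is driven sinusoidally around its mean with amplitude
``E·TV/2`` at the current breathing frequency; lung volume follows through
the single airway resistance, ``R·dVlungs/dt = Pm − Ppl − E·Vlungs``.  The
pleural (= intrathoracic) pressure is exported, in gauge form, to every
intrathoracic compliance of the circulation.  Tidal volume and frequency are
held constant within a breath and retuned only at breath boundaries.
"""
from __future__ import annotations

import math

from ._compat import maybe_jit

__all__ = ["pleural_pressure", "lung_volume_derivative", "intrathoracic_pressure"]


@maybe_jit
def pleural_amplitude(tv: float, freq: float, e_lung: float,
                      r_aw: float) -> float:
    """Pleural swing amplitude (mmHg) that delivers tidal volume ``tv``.

    The quasi-static amplitude is ``E·TV/2``; at a finite breathing
    frequency the airway resistance attenuates the volume response of the
    first-order lung (gain ``E/√(E² + (ωR)²)``), so the respiratory muscles
    must deepen the swing by the reciprocal factor for the commanded tidal
    volume to actually reach the lung.  ``r_aw = 0`` recovers ``E·TV/2``.
    """
    omega = 2.0 * math.pi * freq / 60.0
    return 0.5 * tv * math.sqrt(e_lung * e_lung + (omega * r_aw) ** 2)


@maybe_jit
def pleural_pressure(t_b: float, tv: float, freq: float, e_lung: float,
                     ppl0: float, r_aw: float = 0.0) -> float:
    """Pleural pressure (mmHg gauge) at breath phase ``t_b`` (s).

    ``ppl0`` is the gauge mean pleural pressure (e.g. −6 mmHg); the sine
    starts into inspiration (pressure falling) at ``t_b = 0``.
    """
    amp = pleural_amplitude(tv, freq, e_lung, r_aw)
    return ppl0 - amp * math.sin(2.0 * math.pi * (freq / 60.0) * t_b)


@maybe_jit
def lung_volume_derivative(ppl: float, vlungs: float, r_aw: float,
                           e_lung: float, pm: float = 0.0) -> float:
    """dVlungs/dt (l/s) through the airway resistance."""
    return (pm - ppl - vlungs * e_lung) / r_aw


@maybe_jit
def intrathoracic_pressure(ppl: float) -> float:
    """Intrathoracic pressure = pleural pressure relative to atmosphere."""
    return ppl
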