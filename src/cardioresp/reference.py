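"""Literature reference values for validating graded-cycling simulations.

Steady-state exercise values from the graded isokinetic-cycling studies the
model is parameterised against — chiefly Sullivan et al. (Circulation 1989;
12 healthy subjects, 30 chronic heart-failure patients, +24.5 W / 3 min) —
plus the autonomic-blockade heart-rate responses of Robinson et al.
(Circ Res 1966).  Values are the rest and 73 W endpoints; units as noted.
"""
from __future__ import annotations

from typing import Mapping

__all__ = ["REFERENCE", "compare_rows"]

# {(condition, quantity): (rest value, 73 W value, unit)}
REFERENCE: dict[tuple[str, str], tuple[float | None, float | None, str]] = {
    ("healthy", "hr"): (67.0, 134.0, "bpm"),
    ("healthy", "map"): (92.0, 134.0, "mmHg"),
    ("healthy", "co"): (5.3, 10.2, "l/min"),
    ("healthy", "q_leg"): (0.7, 3.0, "l/min"),
    ("healthy", "tpr"): (0.9, 0.5, "mmHg/(cm3/s)"),
    ("healthy", "r_leg"): (6.5, 1.0, "mmHg/(cm3/s)"),
    ("healthy", "avdiff_central"): (4.5, 10.8, "ml/dl"),
    ("healthy", "avdiff_leg"): (3.1, 15.1, "ml/dl"),
    ("healthy", "vent"): (6.1, 25.5, "l/min"),
    ("hf", "hr"): (85.0, 137.0, "bpm"),
    ("hf", "co"): (4.4, 6.6, "l/min"),
    ("hf", "q_leg"): (0.6, 1.4, "l/min"),
    ("hf", "tpr"): (1.2, 0.6, "mmHg/(cm3/s)"),
    ("hf", "r_leg"): (8.7, 1.6, "mmHg/(cm3/s)"),
    ("hf", "avdiff_central"): (5.9, 14.4, "ml/dl"),
    ("hf", "avdiff_leg"): (5.3, 19.2, "ml/dl"),
    ("hf", "vent"): (9.2, 40.2, "l/min"),
    # single-channel open-loop HR responses (rest -> peak protocol workload)
    ("healthy", "hr_vagal_only"): (57.0, 85.0, "bpm"),
    ("healthy", "hr_sympathetic_only"): (58.0, 66.0, "bpm"),
}


def compare_rows(summaries_by_condition: Mapping[str, list]) -> list[dict]:
    """Juxtapose simulated stage summaries with the reference endpoints.

    ``summaries_by_condition`` maps condition label to the list of
    :class:`~cardioresp.engine.StageSummary` (rest first, 73 W last).
    Returns one row per referenced quantity with the relative error.
    """
    rows = []
    for (cond, qty), (ref_rest, ref_peak, unit) in REFERENCE.items():
        if qty.startswith("hr_"):
            continue  # open-loop entries are handled by the sweep tools
        summaries = summaries_by_condition.get(cond)
        if not summaries:
            continue
        sim_rest = getattr(summaries[0], qty)
        sim_peak = getattr(summaries[-1], qty)
        for stage, ref, sim in (("rest", ref_rest, sim_rest),
                                ("73W", ref_peak, sim_peak)):
            if ref is None:
                continue
            rows.append({
                "condition": cond, "quantity": qty, "stage": stage,
                "unit": unit, "reference": ref, "simulated": round(sim, 3),
                "rel_error": round((sim - ref) / ref, 3),
            })
    return rows
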