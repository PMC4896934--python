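"""Exercise protocols: workload schedules and the metabolic drive they set.

Graded cycling is modelled as a piecewise-constant workload schedule whose
level drives, simultaneously, the baroreflex resetting, the leg muscle
pump, and the metabolic demand: district oxygen uptakes and the respiratory
quotient are affine in workload (fits to graded-cycling gas-exchange data,
with separate coefficients for healthy and heart-failure subjects).  The
resting-regions uptake splits 30% upper body / 32% kidneys / 38% splanchnic.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

from .config import ConditionProfile

__all__ = [
    "WorkloadSchedule", "MetabolicDrive", "graded_protocol", "rest_protocol",
    "oxygen_uptake", "respiratory_quotient", "schedule_state",
    "RESTING_SPLIT",
]

#: Fractions of the resting-regions VO2: upper body, kidneys, splanchnic.
RESTING_SPLIT = (0.30, 0.32, 0.38)


@dataclasses.dataclass(frozen=True)
class WorkloadSchedule:
    """Ordered (start time s, workload W) steps; right-continuous."""

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.steps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("step times must be strictly increasing")
        if any(wl < 0 for _, wl in self.steps):
            raise ValueError("workloads must be >= 0")

    @property
    def duration_hint(self) -> float:
        return self.steps[-1][0] if self.steps else 0.0


def rest_protocol() -> WorkloadSchedule:
    return WorkloadSchedule(((0.0, 0.0),))


def graded_protocol(stage_duration: float = 180.0,
                    workloads: Sequence[float] = (24.5, 49.0, 73.0),
                    ) -> WorkloadSchedule:
    """Rest followed by the graded cycling stages (default +24.5 W / 3 min)."""
    steps = [(0.0, 0.0)]
    steps += [(stage_duration * (i + 1), float(w)) for i, w in enumerate(workloads)]
    return WorkloadSchedule(tuple(steps))


def schedule_state(t: float, schedule: WorkloadSchedule) -> float:
    """Workload (W) at time ``t``; 0 before the first step."""
    wl = 0.0
    for start, w in schedule.steps:
        if t >= start:
            wl = w
        else:
            break
    return wl


@dataclasses.dataclass(frozen=True)
class MetabolicDrive:
    """Per-district O2 uptake (ml/min) and the respiratory quotient."""

    vo2_ub: float
    vo2_kid: float
    vo2_sp: float
    vo2_ll: float
    vo2_rl: float
    rq: float

    @property
    def total_vo2(self) -> float:
        return (self.vo2_ub + self.vo2_kid + self.vo2_sp
                + self.vo2_ll + self.vo2_rl)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.vo2_ub, self.vo2_kid, self.vo2_sp,
                self.vo2_ll, self.vo2_rl)


def oxygen_uptake(wl: float, profile: ConditionProfile) -> MetabolicDrive:
    """Metabolic drive at workload ``wl`` for the profile's condition."""
    if wl < 0:
        raise ValueError("workload must be >= 0")
    vo2_rr = profile.VO2RR_int + profile.VO2RR_slope * wl
    vo2_leg = profile.VO2leg_int + profile.VO2leg_slope * wl
    f_ub, f_kid, f_sp = RESTING_SPLIT
    return MetabolicDrive(
        vo2_ub=f_ub * vo2_rr,
        vo2_kid=f_kid * vo2_rr,
        vo2_sp=f_sp * vo2_rr,
        vo2_ll=vo2_leg,
        vo2_rl=vo2_leg,
        rq=respiratory_quotient(wl, profile),
    )


def respiratory_quotient(wl: float, profile: ConditionProfile) -> float:
    """RQ at workload ``wl`` (affine fit per condition)."""
    if wl < 0:
        raise ValueError("workload must be >= 0")
    return profile.RQ_int + profile.RQ_slope * wl
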