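"""Condition profiles: the complete parameter set of the simulator.

A :class:`ConditionProfile` holds every tunable constant of the model —
cardiac chamber properties, the twelve-compartment vascular network,
ventilation mechanics and control, baroreflex resetting, autonomic effector
gains, metabolic vasodilation gains, and the workload→metabolism relations —
for one subject condition (``healthy`` or ``hf``, i.e. chronic heart
failure).

Profiles are shipped as flat ``name = value`` text fixtures
(``fixtures/healthy.params``, ``fixtures/hf.params``) so every number can be
audited at a glance, and can be serialized back to the same format
bit-exactly (floats are written with ``repr``).

Units follow the source tables: pressures mmHg, volumes cm³, flows cm³/s,
resistances mmHg·s/cm³, compliances cm³/mmHg, inertances mmHg·s²/cm³,
ventilation l/min, blood gas contents ml gas/dl blood, nerve activities
spikes/s.  Conversions (dl→ml, l→cm³, min→s) happen at module boundaries in
the engine.
"""
from __future__ import annotations

import dataclasses
import importlib.resources
import math
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "ConditionProfile",
    "NumericalSettings",
    "PARAM_ORDER",
    "load_profile",
    "validate_profile",
    "loads_profile",
    "dumps_profile",
]


# --------------------------------------------------------------------------
# Parameter tables
# --------------------------------------------------------------------------
# Healthy condition: the full resting parameter assignment.
_HEALTHY: dict[str, float] = {
    # --- cardiac chambers -------------------------------------------------
    "HR_set": 58.0,          # bpm, resting set-point heart rate
    "Cla": 25.0, "Cra": 25.0,            # atrial compliances, cm3/mmHg
    "Vlv0": 5.0, "Vrv0": 5.0,            # ventricular zero-pressure volumes
    "al": 0.033, "bl": 0.034, "cl": 8.0,  # LV passive filling P = a*e^(b*V)+c
    "ar": 0.05, "br": 0.04, "cr": 5.0,    # RV passive filling
    "Elmax": 2.5, "Ermax": 1.1,          # peak systolic elastances, mmHg/cm3
    "Rli": 0.02, "Rri": 0.02,            # ventricular input (AV valve) resistances
    "Rlo": 0.02, "Rro": 0.02,            # ventricular output (semilunar) resistances
    # --- aorta ------------------------------------------------------------
    "Raa": 0.01, "Laa": 5.0e-5, "Caa": 0.8,
    "Rabd": 0.07, "Labd": 5.0e-5, "Cabd": 0.6,
    # --- systemic districts (set-point values; a/v = arterial/venous) -----
    "Ruba_set": 3.52, "Cub": 8.0, "Rubv_set": 0.23, "Vub0_set": 650.0,
    "Rkida_set": 3.62, "Ckid": 15.0, "Rkidv_set": 0.3, "Vkid0_set": 150.0,
    "Rspa_set": 2.69, "Csp": 55.0, "Rspv_set": 0.18, "Vsp0_set": 1300.0,
    "Rlla_set": 12.6, "Cll": 9.5, "Rllv_set": 0.6, "Vll0_set": 175.0,
    "Rrla_set": 12.6, "Crl": 9.5, "Rrlv_set": 0.6, "Vrl0_set": 175.0,
    # --- venae cavae ------------------------------------------------------
    "Csup": 15.0, "Rsup": 0.06,
    "Cinfext": 25.0, "Cinfint": 2.0, "Rinfext": 0.01, "Rinfint": 0.015,
    # --- pulmonary circulation -------------------------------------------
    "Rcp": 0.03, "Cap": 1.0, "Rap": 0.075, "Lap": 3.6e-5, "Vap0": 90.0,
    "Rvp": 0.005, "Cvp": 5.0, "Vvp0": 580.0,
    "weight": 76.0,          # kg; total blood volume = blood_per_kg * weight
    "blood_per_kg": 70.0,    # ml/kg, physiological norm
    # --- ventilation mechanics and control --------------------------------
    "K_DV": 0.8,             # effective tidal-volume fraction (1 - dead space/TV)
    "P_CO2tr": 36.75,        # mmHg, CO2 threshold of the ventilation drive
    "E_lung": 2.0,           # mmHg/l, lung elastance
    "P_CO2I": 0.0,           # mmHg, inspired CO2
    "PIMmax": 0.562,         # mmHg/W, intramuscular pump pressure per watt
    "Ppl0": 754.0,           # mmHg absolute; gauge mean pleural pressure = Ppl0-760
    "P_O2I": 150.0,          # mmHg, inspired O2
    "ps": 0.02,              # pulmonary shunt fraction
    "R_aw": 1.0,             # mmHg/(l/s), airway resistance
    "alpha": 30.0,           # l/(min*mmHg), hypoxic ventilation gain
    "beta": -0.055,          # 1/mmHg
    "gamma": 2.0,            # l/(min*mmHg), CO2 ventilation gain
    "delta": 0.274,          # min/l, Freq = delta*Vent + eps
    "eps": 17.75,            # 1/min
    "peak_VO2": 34.0,        # ml/min/kg, used by the Wasserman dead-space relation
    "V_Eexp": 2.2,           # l, end-expiratory alveolar volume
    # --- baroreflex afferent/efferent and exercise resetting --------------
    "A": 0.242,              # mmHg/W, Paa_set increase per watt
    "B": 0.12,               # spikes/(W*s), sympathetic stimulation per watt
    "C": -0.041,             # spikes/(W*s), vagal withdrawal per watt
    "D": -0.044,             # spikes/(W*s), decrease of Fev upper limit per watt
    "ka": 11.758,            # mmHg
    "kes": 0.0675,           # s
    "kev": 7.06,             # spikes/s
    "Fes0": 16.11, "Fes_inf": 2.10,      # spikes/s
    "Fev0": 3.2, "Fev_inf0": 6.3,        # spikes/s
    "Paa_set0": 90.0,        # mmHg
    "tau_p": 2.076, "tau_z": 6.37,       # s, afferent lead-lag filter
    "Fas_min": 2.52, "Fas_max": 47.78,   # spikes/s (Ursino 1998)
    "D_Hs": 2.0, "D_Hv": 0.2,            # s, efferent pure delays (Ursino 1998)
    # --- sympathetic effector gains ---------------------------------------
    "C_TCs": -0.09, "C_TCv": 0.07,       # s/(spikes/s)
    "C_Elmaxs": 0.61, "C_Ermaxs": 0.133,
    "C_Rubas": 1.16, "C_Rkidas": 1.10, "C_Rspas": 0.95,
    "C_Rllas": 2.4, "C_Rrlas": 2.4,
    "C_Vub0s": -28.1, "C_Vkid0s": -6.5, "C_Vsp0s": -228.3,
    "C_Vll0s": -7.8, "C_Vrl0s": -7.8,
    # --- metabolic control -------------------------------------------------
    "C_RubaMet": 0.73, "C_RkidaMet": 0.69, "C_RspaMet": 0.6,
    "C_RllaMet": 1.5, "C_RrlaMet": 1.5,
    "C_RubvMet": 0.046, "C_RkidvMet": 0.06, "C_RspvMet": 0.036,
    "C_RllvMet": 0.12, "C_RrlvMet": 0.12,
    "C_O2ubvRef": 14.0, "C_O2kidvRef": 17.5, "C_O2spvRef": 15.0,
    "C_O2llvRef": 14.0, "C_O2rlvRef": 14.0,  # ml O2/dl blood
    "k_MET": 1.8,            # dl/ml
    "S0": 0.27,              # basal fraction of arterial resistance
    "T_Met": 2.0,
    "T_Elmax": 8.0, "T_Ermax": 8.0, "T_Ris": 6.0,
    "T_TCs": 2.0, "T_TCv": 1.5, "T_Vis": 20.0,   # s
    # --- workload -> metabolism (graded cycling fits) ----------------------
    "VO2RR_int": 196.0, "VO2RR_slope": 0.0,      # resting regions, ml/min
    "VO2leg_int": 20.23, "VO2leg_slope": 5.87,   # per leg, ml/min
    "RQ_int": 0.859, "RQ_slope": 0.0014,
}

# Heart failure: every entry that differs from healthy.
_HF_OVERRIDES: dict[str, float] = {
    "HR_set": 85.0,
    "Elmax": 1.5, "Vlv0": 25.0,
    "al": 0.031, "bl": 0.031, "cl": 8.0,
    "Ruba_set": 4.72, "Rkida_set": 4.88, "Rspa_set": 3.62,
    "Rlla_set": 8.52, "Rrla_set": 8.52,
    "Rap": 0.175,
    "K_DV": 0.57, "E_lung": 2.8, "peak_VO2": 15.0,
    "A": 0.3517, "B": 0.02, "Paa_set0": 93.0,
    "C_TCs": -0.0594, "C_TCv": 0.0462,
    "C_Elmaxs": 0.2,
    "C_Rubas": 1.62, "C_Rkidas": 1.53, "C_Rspas": 1.32,
    "C_Rllas": 4.06, "C_Rrlas": 4.06,
    "C_Vkid0s": -6.1,
    "C_O2ubvRef": 12.0, "C_O2kidvRef": 15.5, "C_O2spvRef": 13.0,
    "C_O2llvRef": 12.0, "C_O2rlvRef": 12.0,
    "VO2RR_int": 201.06, "VO2RR_slope": 2.76,
    "VO2leg_int": 28.87, "VO2leg_slope": 3.83,
    "RQ_int": 0.877, "RQ_slope": 0.006,
}

#: Canonical packing order of the parameter vector fed to the engine.
PARAM_ORDER: tuple[str, ...] = tuple(_HEALTHY.keys())

# Index constants (I_<NAME>) used by the numerical kernels to address the
# packed parameter array.  Generated from PARAM_ORDER so config and engine
# can never disagree on the layout.
_g = globals()
for _i, _name in enumerate(PARAM_ORDER):
    _g["I_" + _name.upper()] = _i
N_PARAMS = len(PARAM_ORDER)


class ConfigurationError(ValueError):
    """Raised for unknown parameter names or incomplete profiles."""


@dataclasses.dataclass
class ConditionProfile:
    """Complete parameter vector for one subject condition."""

    condition: str
    values: dict[str, float]

    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["values"][name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_array(self) -> np.ndarray:
        """Pack the profile into the engine's flat float64 vector."""
        return np.array([self.values[n] for n in PARAM_ORDER], dtype=np.float64)

    def replace(self, **overrides: float) -> "ConditionProfile":
        unknown = set(overrides) - set(self.values)
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        vals = dict(self.values)
        vals.update({k: float(v) for k, v in overrides.items()})
        return ConditionProfile(self.condition, vals)


@dataclasses.dataclass
class NumericalSettings:
    """Integration and summarising settings (artifact plumbing, not physiology)."""

    dt: float = 2.5e-4            # s, fixed integration step
    stage_duration: float = 300.0  # s per workload stage, long enough for the
    #                                slow gas stores to reach periodic steady state
    summary_cycles: int = 15       # cardiac cycles averaged for steady-state summaries
    ss_tol: float = 0.005          # relative cycle-to-cycle change of MAP/CO for convergence
    decimation: int = 40           # record the time series every `decimation` steps

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.summary_cycles < 1:
            raise ConfigurationError("summary_cycles must be >= 1")


# --------------------------------------------------------------------------
# Loading / serializing
# --------------------------------------------------------------------------
def _fixture_path(condition: str) -> Path:
    res = importlib.resources.files("cardioresp") / "fixtures" / f"{condition}.params"
    return Path(str(res))


def loads_profile(text: str) -> ConditionProfile:
    """Parse the flat ``name = value`` profile format."""
    condition = ""
    values: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"line {lineno}: expected 'name = value'")
        name, _, val = (s.strip() for s in line.partition("="))
        if name == "condition":
            condition = val
            continue
        if name not in _HEALTHY:
            raise ConfigurationError(f"line {lineno}: unknown parameter {name!r}")
        values[name] = float(val)
    missing = set(_HEALTHY) - set(values)
    if missing:
        raise ConfigurationError(f"missing parameter(s): {sorted(missing)}")
    if condition not in ("healthy", "hf"):
        raise ConfigurationError(f"missing or invalid condition label: {condition!r}")
    return ConditionProfile(condition, values)


def dumps_profile(profile: ConditionProfile) -> str:
    lines = [f"condition = {profile.condition}"]
    lines += [f"{n} = {profile.values[n]!r}" for n in PARAM_ORDER]
    return "\n".join(lines) + "\n"


def load_profile(
    condition: str,
    overrides: Mapping[str, float] | None = None,
    path: str | Path | None = None,
) -> ConditionProfile:
    """Load a complete condition profile.

    Parameters
    ----------
    condition
        ``"healthy"`` or ``"hf"``.  With ``path`` given the file's own
        condition label wins and this argument is ignored.
    overrides
        Optional ``{parameter: value}`` map applied on top of the fixture.
    path
        Optional profile file; defaults to the packaged fixture.
    """
    if path is None:
        if condition not in ("healthy", "hf"):
            raise ConfigurationError(f"unknown condition {condition!r}")
        path = _fixture_path(condition)
    profile = loads_profile(Path(path).read_text())
    if overrides:
        profile = profile.replace(**overrides)
    return profile


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------
_POSITIVE = [
    "Cla", "Cra", "Elmax", "Ermax", "Rli", "Rri", "Rlo", "Rro",
    "Raa", "Laa", "Caa", "Rabd", "Labd", "Cabd",
    "Ruba_set", "Cub", "Rubv_set", "Rkida_set", "Ckid", "Rkidv_set",
    "Rspa_set", "Csp", "Rspv_set", "Rlla_set", "Cll", "Rllv_set",
    "Rrla_set", "Crl", "Rrlv_set",
    "Csup", "Rsup", "Cinfext", "Cinfint", "Rinfext", "Rinfint",
    "Rcp", "Cap", "Rap", "Lap", "Rvp", "Cvp",
    "weight", "blood_per_kg", "E_lung", "R_aw", "ka", "gamma", "delta",
    "tau_p", "k_MET", "V_Eexp",
    "T_Met", "T_Elmax", "T_Ermax", "T_Ris", "T_TCs", "T_TCv", "T_Vis",
]
_NONNEG = ["Vlv0", "Vrv0", "Vub0_set", "Vkid0_set", "Vsp0_set",
           "Vll0_set", "Vrl0_set", "Vap0", "Vvp0", "PIMmax", "Fas_min",
           "C_O2ubvRef", "C_O2kidvRef", "C_O2spvRef", "C_O2llvRef", "C_O2rlvRef"]


def validate_profile(profile: ConditionProfile) -> list[str]:
    """Check every type invariant; return human-readable violations.

    Reports, never raises: an empty list means the profile is valid.
    """
    v = profile.values
    out: list[str] = []
    for name in _POSITIVE:
        if not (v[name] > 0) or not math.isfinite(v[name]):
            out.append(f"{name} must be > 0 (got {v[name]!r})")
    for name in _NONNEG:
        if not (v[name] >= 0) or not math.isfinite(v[name]):
            out.append(f"{name} must be >= 0 (got {v[name]!r})")
    if not (0.0 <= v["S0"] <= 1.0):
        out.append(f"S0 must lie in [0, 1] (got {v['S0']!r})")
    if not (0.0 < v["K_DV"] <= 1.0):
        out.append(f"K_DV must lie in (0, 1] (got {v['K_DV']!r})")
    if not (0.0 <= v["ps"] < 1.0):
        out.append(f"ps must lie in [0, 1) (got {v['ps']!r})")
    if not (v["Fes0"] > v["Fes_inf"] > 0):
        out.append("Fes0 > Fes_inf > 0 violated")
    if not (v["Fas_max"] > v["Fas_min"] >= 0):
        out.append("Fas_max > Fas_min >= 0 violated")
    if not (v["HR_set"] > 0):
        out.append(f"HR_set must be > 0 (got {v['HR_set']!r})")
    if profile.condition not in ("healthy", "hf"):
        out.append(f"condition must be healthy or hf (got {profile.condition!r})")
    return out


def builtin_table(condition: str) -> dict[str, float]:
    """The in-source parameter table (used to regenerate fixtures and by tests)."""
    if condition == "healthy":
        return dict(_HEALTHY)
    if condition == "hf":
        merged = dict(_HEALTHY)
        merged.update(_HF_OVERRIDES)
        return merged
    raise ConfigurationError(f"unknown condition {condition!r}")


def write_fixtures(directory: str | Path) -> None:
    """Regenerate the shipped .params fixtures from the in-source tables."""
    directory = Path(directory)
    for cond in ("healthy", "hf"):
        prof = ConditionProfile(cond, builtin_table(cond))
        (directory / f"{cond}.params").write_text(dumps_profile(prof))
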