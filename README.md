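# cardioresp

A closed-loop, lumped-parameter simulator of the human cardiorespiratory
response to aerobic (cycling) exercise, in healthy subjects and in chronic
heart failure (HF).

Exercise intolerance in heart failure emerges from the interaction of many
control loops — chronotropic and inotropic reserve, vascular tone,
ventilation, oxygen extraction — and no single measurement isolates them.
This simulator couples all of the relevant subsystems in one deterministic
model so that each mechanism, and each HF impairment, can be switched,
swept, and quantified:

* **Circulation** — four heart chambers (atria as passive compliances,
  ventricles as time-varying elastances `P = E(t)·(V − V0)` blended with an
  exponential passive filling law `P = a·e^{bV} + c`), a systemic tree split
  into exercising (legs) and non-exercising (upper body, kidneys,
  splanchnic) districts, venae cavae with a Starling resistor on the
  intrathoracic inferior vena cava, and a two-compartment pulmonary bed.
  Diode valves; a 1 Hz antiphase leg muscle pump
  `P_IM = P_IMmax·WL·(1 + sin 2πt)` rectified by the leg venous valves.
* **Respiration** — sinusoidal pleural-pressure drive, first-order lung
  mechanics `R·V̇ + E·V = Pm − Ppl`, with the pleural pressure exported as
  intrathoracic pressure to every intrathoracic compliance (the mechanical
  heart–lung interaction that modulates venous return).
* **Gas exchange** — Hill-type O₂ and power-law CO₂ dissociation curves,
  an alveolar mass balance with blood-side capacitance `863·Vap·dC/dP` and
  a 2% pulmonary shunt, and well-mixed tissue stores per district with
  O₂ consumption and `RQ`-scaled CO₂ production.
* **Baroreflex with exercise resetting** — a lead-lag afferent filter on
  transmural aortic pressure, logistic afferent firing about a set point
  that rises with workload (`Paa_set = Paa_set0 + A·WL`), sympathetic
  (`+B·WL`) and vagal (withdrawal `C·WL`, shrinking ceiling `D·WL`)
  efferents with pure delays, and per-effector static + first-order dynamic
  responses for heart period, contractilities, arterial resistances and
  venous unstressed volumes.
* **Metabolic control with functional sympatholysis** — each district
  senses its venous O₂ content through a sigmoid; hypoxia dilates
  arterial and venous resistances, and gates the sympathetic
  vasoconstriction by `sf¹⁰`, so active muscle escapes vasoconstriction:
  `Ria = Ria_set·S0 + [Ria_set·(1−S0) + ΔRia_s]·sf¹⁰ + ΔRia_met`.
* **Ventilation control** — minute ventilation from upper-body arterial
  gas tensions, `Vent = α·e^{β·P_O2}·(P_CO2 − P_CO2tr) + γ·(P_CO2 −
  P_CO2tr)`, split into frequency and tidal volume, with a dead-space
  correction tied to peak aerobic capacity (Wasserman relation).

Every parameter of both condition profiles is shipped as an auditable flat
text fixture (`src/cardioresp/fixtures/{healthy,hf}.params`), keyed to the
published graded-cycling parameter tables.

## Worked example

Simulate the graded cycling protocol (rest, then 24.5 → 49 → 73 W) for a
healthy subject, with each stage run to periodic steady state and averaged
over the final 15 cardiac cycles:

```bash
cardioresp simulate --condition healthy --protocol graded \
    --stage-duration 300 --out out/healthy
```

```
WL   0.0 W | HR   60.8 bpm | MAP   84.3 mmHg | CO  4.33 l/min | Qleg  0.32 l/min | Vent   5.5 l/min
WL  24.5 W | HR   72.7 bpm | MAP   82.8 mmHg | CO  5.57 l/min | Qleg  1.34 l/min | Vent  11.7 l/min
WL  49.0 W | HR   86.6 bpm | MAP   80.0 mmHg | CO  6.87 l/min | Qleg  2.19 l/min | Vent  17.7 l/min
WL  73.0 W | HR  103.5 bpm | MAP   86.9 mmHg | CO  8.15 l/min | Qleg  2.81 l/min | Vent  23.6 l/min
```

Reading the 73 W row: heart rate has risen through vagal withdrawal and
sympathetic stimulation; cardiac output nearly doubles from rest; the
single-leg blood flow `Qleg` rises ninefold as metabolic vasodilation and
sympatholysis collapse leg arterial resistance from 12.6 to ≈1.9
mmHg·s/cm³; minute ventilation has risen with the CO₂ load of exercise
(`RQ` = 0.96 at 73 W).  Internally the run conserves blood volume to
<10⁻⁶ and closes the Fick principle (`CO × central a-v O₂ difference` =
prescribed V̇O₂) to <1% at every stage.  The same command with
`--condition hf` shows the heart-failure phenotype: lower leg perfusion,
higher ventilation (37.3 vs 23.6 l/min at 73 W), blunted contractile
reserve.

The command writes `time_series.csv`, per-cycle and per-breath tables, and
`summary.json`.  Sub-model sweeps are available as
`cardioresp baroreflex-curve` (open-loop stimulus–response with workload
resetting) and `cardioresp metabolic-curve` (resistance vs venous O₂
content, with or without sympathetic tone), and
`cardioresp validate --out report.json` juxtaposes both conditions with
literature endpoints from graded-cycling studies.

In Python:

```python
import cardioresp as cr

profile = cr.load_profile("healthy")
record = cr.simulate(profile, cr.graded_protocol(300.0))
for stage in cr.steady_state_summary(record):
    print(stage.wl, round(stage.hr, 1), round(stage.co, 2))
```

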