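# Methods

## Model overview

The simulator advances one deterministic state vector (58 entries) with a
fixed-step classical Runge–Kutta (RK4) integrator: 16 blood volumes, two
inertance flows, lung volume, two alveolar gas tensions, ten district
venous gas contents, the baroreflex afferent filter output, 24 controller
deviation states, and two phase clocks (cardiac cycle, breath).  All
pressures are gauge (atmosphere = 0); the tabulated absolute mean pleural
pressure (754 mmHg) is used as −6 mmHg gauge.  Units follow the parameter
tables: mmHg, cm³, s for hemodynamics; l and l/min for ventilation;
ml gas/dl blood for contents (converted to ml/ml at the gas-flux
boundaries); the constant 863 mmHg converts STPD content flux to BTPS
partial-pressure volume flux.

Discrete events run between steps:

* **Cardiac cycle boundary** (`t_c ≥ TC`): the controlled heart period
  `TC = TC_set + ΔTCs + ΔTCv` is latched for the whole next cycle
  (clamped to [0.25, 3] s), and per-cycle channel means are emitted.
* **Breath boundary**: the ventilation controller reads the breath-mean
  upper-body arterial gas tensions (accumulated as contents, inverted once
  through the dissociation curves) and retunes `Vent`, `Freq`, `TV`;
  mid-breath retuning is forbidden, which keeps the pleural waveform
  continuous in value.
* **Efferent delays**: sympathetic and vagal activities pass through pure
  delay lines (ring buffers) of 2 s and 0.2 s before the effector static
  responses; within one step the delayed values, and hence the static
  responses, are frozen.

## Cardiac chambers

Atria are passive compliances (`P = V/C + Pintr`, zero unstressed volume —
none is tabulated).  Ventricles blend the printed end-member laws with a
smooth activation waveform φ(t_c) = sin²(π·t_c/T_sys), T_sys = 0.3·√TC:

    P = φ·E_max,eff·(V − V0) + (1 − φ)·(a·e^{bV} + c) + Pintr

φ = 1 recovers the systolic elastance law, φ = 0 the exponential filling
law; the blend guarantees continuity through the cycle.  This is standard
elastance-model practice; only the end members are published.

## Network topology

The figure-level topology is: aortic valve → ascending aorta (upper body
branches here) → inertial segment (R = Raa + Rabd, L = Laa + Labd) →
descending aorta → kidneys, splanchnic bed, and both legs in parallel.
Venous return: upper body → SVC → right atrium; kidneys/splanchnic/legs →
extrathoracic IVC → (Starling resistor, external pressure = Pintr) →
intrathoracic IVC → right atrium.  Pulmonary: RV → (valve + characteristic
resistance) → arterial compartment → (Rap, Lap) → venous compartment → LA.
Merging the two printed aortic series impedances into one segment uses all
printed parameters with the two printed aortic compartments; the split
between them is not identifiable from steady pressures anyway.

Intrathoracic compartments receiving Pintr: both atria and ventricles,
ascending aorta, SVC, intrathoracic IVC, both pulmonary compartments.

Heart valves and leg venous valves are exact piecewise diodes (ties give
zero flow); the fixed 0.25 ms step crosses switching times without special
handling, and step-halving checks confirm the summaries are insensitive.

**Muscle pump.** Each leg is a single lumped compartment (one tabulated
compliance), so the intramuscular pressure cannot be applied to a separate
venous sub-compartment.  Applying it to the whole compartment would raise
mean leg pressure by `P_IMmax·WL` (≈ +41 mmHg at 73 W) against arterial
inflow and collapse leg perfusion.  It is therefore applied to the deep
venous outflow branch: the valve upstream pressure is
`P_leg + P_IM(t)`, so contraction ejects venous blood through the valve
and relaxation lets the compartment refill through the artery — the
classical muscle-pump function with a lumped leg.

**Total blood volume** is set from body weight at 70 ml/kg (5320 cm³ at
76 kg); the initial state places compartments at plausible resting
pressures and closes the budget through the splanchnic reservoir, so
conservation starts exact.  The closed loop then finds its own operating
point; stressed/unstressed split at t=0 only affects the transient.

## Respiration

The pleural drive is sinusoidal about its mean.  The tabulated form
`E·TV/2` for its amplitude is the quasi-static limit of the first-order
lung `R·V̇ + E·V = −Ppl`; at exercise breathing frequencies that amplitude
would deliver only ≈55–70% of the commanded tidal volume, leaving the
ventilation controller unable to realise its own output.  The amplitude is
therefore frequency-compensated,

    amp = (TV/2)·sqrt(E² + (ω·R)²),  ω = 2π·Freq/60,

which reduces to `E·TV/2` as ω→0 and delivers exactly TV on the periodic
orbit (verified by test).  HF keeps the same drive with its stiffer lung
(E = 2.8 mmHg/l), producing the wider intrathoracic pressure swings of the
HF phenotype.

Alveolar ventilation is `K_DV · dVlungs/dt`, with `K_DV` the *effective*
fraction of the breath (0.8 healthy, 0.57 HF) — the complement of the
Wasserman dead-space/tidal-volume ratio predicted from peak aerobic
capacity (−0.012·peakV̇O₂ + 0.611; 0.203 and 0.431 for the two profiles).
Inspiration/expiration switching follows the sign of dVlungs/dt; the
alveolar gas volume is the end-expiratory volume (2.2 l, a physiological
choice — no value is tabulated) plus the effective excursion above the
breath-start lung volume.

## Gas transport

O₂ content: Hill curve, n = 2.7, P50 = 26.6 mmHg, Hb capacity
20.1 ml/dl, dissolved 0.003 ml/dl/mmHg.  CO₂ content: monotone power law
`48·(P/40)^0.55` ml/dl (48/51.8 ml/dl at the 40/46 mmHg norms, slope
0.66 ml/dl/mmHg at 40 mmHg).  Both are strictly increasing with exact
inverses (Newton with bisection safeguard for O₂, analytic for CO₂); the
curve constants are model constants pinned by regression tests.

The alveolar balance uses effective capacitance
`V_alv + 863·Vap·dC/dP` (Vap the instantaneous pulmonary arterial blood
volume) and blood flux `863·(1−ps)·Qpv·(C_venous_in − C_equilibrated)`;
the fresh-gas term `V̇A·(P_I − P_alv)` acts during inspiration only.  At
periodic steady state this reduces to the alveolar gas equation
`V̇A·(P_I − P_A) = 863·Q·(Ca − Cv)`.  Blood leaving the lungs is fully
equilibrated with the alveoli; systemic arterial content mixes in the 2%
shunt of mixed venous blood.  Mixed venous content is the flow-weighted
average of the five district venous outflows (vena-cava storage delay is
neglected; it cannot affect periodic steady states).  District stores are
well mixed with venous content equal to tissue content; reverse arterial
flow carries district content (upwind), which keeps the balance exact.

## Autonomic control

Afferent: lead-lag filter `τp·Ṗ = Paa + τz·Ṗaa − P` on the *transmural*
ascending-aortic pressure (the printed baroreflex input excludes the
intrathoracic pressure); `Ṗaa` is available analytically from the volume
derivative.  The filter's high-frequency gain τz/τp ≈ 3 makes the reflex
pulse-sensitive, as baroreceptors are.

Firing and efferents (logistic interpolations between their saturation
levels, as in the parent baroreflex model):

    Fas = (Fas_min + Fas_max·e^z)/(1+e^z),      z = (P − Paa_set)/ka
    Fes = Fes_inf + (Fes0 − Fes_inf)·e^{−kes·Fas} + B·WL
    Fev = (Fev0 + Fev_inf·e^w)/(1+e^w) + C·WL,  w = (Fas − Fas0)/kev
    Fev_inf = Fev_inf0 + D·WL,   Fev clamped at 0

Exercise resetting acts through the set-point shift `Paa_set0 + A·WL` and
the efferent offsets; at high workload `Fev → Fev_inf0 + (C+D)·WL ≈ 0`
near 73 W — complete vagal withdrawal regardless of pressure, which is the
stated design intent of the `D` term.

Effector static responses: vagal, linear in the delayed activity
(`C_Hv·(Fev_d − Fev_set)`); sympathetic, logarithmically compressive and
exactly zero at the reference activity:

    sf_Hs = C_Hs·[ln(Fes_d − Fes_inf + 1) − ln(Fes_set − Fes_inf + 1)]

(the log form of the parent model; the printed variant is unevaluable at
its own set point and was treated as typographically corrupted).
`Fes_set`/`Fev_set` are fixed at the *rest* central values (zero workload,
filtered pressure at the rest set point).  This anchoring is what makes
resetting effective: at rest the set-point contract holds exactly (every
effector at its set value when `Paa = Paa_set0`, asserted by test), while
at workload the operating values move away from rest — the single-channel
open-loop sweeps then reproduce the blockade-experiment endpoints (vagal
channel 58→84 bpm, sympathetic channel 58→65 bpm, rest→73 W).  Referencing
the set activities to the current workload instead would zero the response
at every operating point and freeze the heart rate at rest values.

Effector channels (gains per the tables; channels without printed gains do
not exist): heart period (sympathetic + vagal, separate time constants),
both ventricular elastances, five district arterial resistances, five
unstressed volumes.  Each is a first-order lag `dΔH/dt = (sf − ΔH)/T_H`.

## Metabolic control and sympatholysis

Per district, `sf = 1 − 1/(1 + e^{k·(C_O2iv − C_ref/2)})` (midpoint at half
the reference content; ≈1 at the reference, so resting resistances sit at
their set points), first-order dynamics with gain `C_RiMet·(sf − 1) ≤ 0`
(pure vasodilation), venous resistance `Riv = Riv_set + ΔRiv_met`, and
arterial resistance

    Ria = Ria_set·S0 + [Ria_set·(1−S0) + ΔRia_s]·sf¹⁰ + ΔRia_met

The `sf¹⁰` gate is the functional-sympatholysis mechanism: sympathetic
vasoconstriction collapses steeply once venous O₂ falls below ≈ C_ref/2.
Resistances are floored at 5% of their basal values (`Ria_set·S0`); the
floor never engages with the shipped profiles.

## Exercise protocol and metabolic drive

Workload schedules are piecewise-constant; one workload value drives the
set-point shift, the efferent offsets, the muscle pump, and the metabolic
demand simultaneously.  Demand is affine in workload per condition
(healthy: resting regions 196 ml/min split 30/32/38% upper
body/kidneys/splanchnic, per-leg `5.87·WL + 20.23`; HF: `2.76·WL + 201.06`
resting, per-leg `3.83·WL + 28.87`; RQ `0.0014·WL + 0.859` and
`0.006·WL + 0.877`).

## Numerics

Fixed step 0.25 ms.  The stiffest element is the pulmonary inertance
branch (`Rap/Lap ≈ 4.9·10³ s⁻¹` in HF), which bounds the explicit-RK4
step; 0.25 ms leaves a ≈2× stability margin.  Controller and gas states
are orders of magnitude slower and ride along in the same vector.
Stage duration defaults to 300 s: cycle-mean hemodynamics converge within
≈60 s, but the whole-body CO₂ stores (≈2.5 l dissolved/bound) have a
multi-minute time constant and need the longer stage to settle; the
convergence criterion (relative change of 15-cycle-mean MAP and CO below
0.5%) is reported per stage.  Summaries average the final 15 cardiac
cycles.  Halving the step changes stage summaries by well under 1%
(asserted by test).  Runs are bit-deterministic; there is no random number
anywhere in the model.

The integrator core is JIT-compiled with numba (a pure-Python fallback
path exists and is exercised by the same code); a full two-condition
graded protocol takes ≈20 s after compilation.

## What the condition profiles do and do not represent

The two profiles are population-average parameterisations of graded-
cycling study cohorts (healthy subjects and moderate chronic heart
failure), not patient-specific models.  Passing tests therefore show that
the coupled mechanisms reproduce cohort-level steady-state exercise
physiology under the tabulated parameters; they do not validate transient
kinetics (stage transitions are not fitted), anaerobic metabolism beyond
the linear RQ fits, posture/gravity effects, or ventilation–perfusion
mismatch — all outside the model's scope.

## Known limitations

* **Peak-exercise chronotropic ceiling.** With the tabulated reflex gains
  the heart-period response is bounded: maximal vagal withdrawal
  contributes `C_TCv·(0 − Fev_set) ≈ −0.33 s` and maximal sympathetic
  drive ≈ −0.18 s, so closed-loop heart rate at 73 W lies in ≈100–114 bpm
  for any arterial pressure.  Literature endpoints for healthy cycling at
  that load (≈134 bpm, CO ≈ 10 l/min) are above this ceiling; the
  simulator's 73 W healthy operating point (HR ≈ 103 bpm, CO ≈ 8.2 l/min)
  is the self-consistent fixed point of the implemented equations, and the
  Fick-coupled quantities (central a-v difference, TPR) shift accordingly.
* **HF leg perfusion.** The reported HF endpoint pair (leg flow
  1.4 l/min with a-v difference 19.2 ml/dl at 73 W) is not a fixed point
  of the sympatholysis equations: at that flow the required a-v difference
  would exceed the arterial O₂ content, and a collapsed venous content
  opens the `sf¹⁰` gate and drops leg resistance to its basal level.  The
  model settles at ≈2.3 l/min with venous O₂ ≈ 6.6 ml/dl.
* Atrial contraction, pericardium, coronary flow, gravity, pH/Haldane–Bohr
  coupling, and lactate buffering are not modelled.
* The ventilation controller has no exercise feedforward; all drive is
  chemoreflex, so arterial P_CO2 rises above rest at heavy load.
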