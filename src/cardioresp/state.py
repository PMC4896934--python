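"""Flat state-vector layout shared by the numerical kernels.

The closed-loop model integrates one float64 vector of length :data:`NX`:
blood volumes (cm³), two inertance flows (cm³/s), lung volume (l), alveolar
gas tensions (mmHg), district venous gas contents (ml/dl), the baroreflex
afferent filter output (mmHg), the autonomic effector deviations, the
metabolic resistance deviations, and the cardiac / breath phase clocks (s).
"""

# chamber and compartment volumes, cm3
VLA, VLV, VRA, VRV = 0, 1, 2, 3
VAA, VABD = 4, 5                       # ascending / descending aorta
VUB, VKID, VSP, VLL, VRL = 6, 7, 8, 9, 10   # districts
VSUP, VINFE, VINFI = 11, 12, 13        # SVC, IVC outside / inside chest
VAP, VVP = 14, 15                      # pulmonary arterial / venous

QAO = 16   # aortic segment inertance flow, cm3/s
QPA = 17   # pulmonary arterial inertance flow, cm3/s

VLUNGS = 18           # l
PO2ALV, PCO2ALV = 19, 20   # mmHg

# district venous gas contents, ml/dl; order: ub, kid, sp, ll, rl
CO2V0, CCO2V0 = 21, 26

PFILT = 31            # baroreflex afferent filter output, mmHg

# autonomic effector first-order deviations
DTCS, DTCV = 32, 33
DELMAX, DERMAX = 34, 35
DRAS0 = 36            # ΔRia_s: ub, kid, sp, ll, rl -> 36..40
DV00 = 41             # ΔVi0:   ub, kid, sp, ll, rl -> 41..45
DRAMET0 = 46          # ΔRia_met per district -> 46..50
DRVMET0 = 51          # ΔRiv_met per district -> 51..55

TCPH = 56             # cardiac phase clock t_c ∈ [0, TC)
TBPH = 57             # breath phase clock t_b ∈ [0, 60/Freq)

NX = 58

N_DISTRICTS = 5
DISTRICTS = ("upper_body", "kidneys", "splanchnic", "left_leg", "right_leg")
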