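condition = hf
HR_set = 85.0
Cla = 25.0
Cra = 25.0
Vlv0 = 25.0
Vrv0 = 5.0
al = 0.031
bl = 0.031
cl = 8.0
ar = 0.05
br = 0.04
cr = 5.0
Elmax = 1.5
Ermax = 1.1
Rli = 0.02
Rri = 0.02
Rlo = 0.02
Rro = 0.02
Raa = 0.01
Laa = 5e-05
Caa = 0.8
Rabd = 0.07
Labd = 5e-05
Cabd = 0.6
Ruba_set = 4.72
Cub = 8.0
Rubv_set = 0.23
Vub0_set = 650.0
Rkida_set = 4.88
Ckid = 15.0
Rkidv_set = 0.3
Vkid0_set = 150.0
Rspa_set = 3.62
Csp = 55.0
Rspv_set = 0.18
Vsp0_set = 1300.0
Rlla_set = 8.52
Cll = 9.5
Rllv_set = 0.6
Vll0_set = 175.0
Rrla_set = 8.52
Crl = 9.5
Rrlv_set = 0.6
Vrl0_set = 175.0
Csup = 15.0
Rsup = 0.06
Cinfext = 25.0
Cinfint = 2.0
Rinfext = 0.01
Rinfint = 0.015
Rcp = 0.03
Cap = 1.0
Rap = 0.175
Lap = 3.6e-05
Vap0 = 90.0
Rvp = 0.005
Cvp = 5.0
Vvp0 = 580.0
weight = 76.0
blood_per_kg = 70.0
K_DV = 0.57
P_CO2tr = 36.75
E_lung = 2.8
P_CO2I = 0.0
PIMmax = 0.562
Ppl0 = 754.0
P_O2I = 150.0
ps = 0.02
R_aw = 1.0
alpha = 30.0
beta = -0.055
gamma = 2.0
delta = 0.274
eps = 17.75
peak_VO2 = 15.0
V_Eexp = 2.2
A = 0.3517
B = 0.02
C = -0.041
D = -0.044
ka = 11.758
kes = 0.0675
kev = 7.06
Fes0 = 16.11
Fes_inf = 2.1
Fev0 = 3.2
Fev_inf0 = 6.3
Paa_set0 = 93.0
tau_p = 2.076
tau_z = 6.37
Fas_min = 2.52
Fas_max = 47.78
D_Hs = 2.0
D_Hv = 0.2
C_TCs = -0.0594
C_TCv = 0.0462
C_Elmaxs = 0.2
C_Ermaxs = 0.133
C_Rubas = 1.62
C_Rkidas = 1.53
C_Rspas = 1.32
C_Rllas = 4.06
C_Rrlas = 4.06
C_Vub0s = -28.1
C_Vkid0s = -6.1
C_Vsp0s = -228.3
C_Vll0s = -7.8
C_Vrl0s = -7.8
C_RubaMet = 0.73
C_RkidaMet = 0.69
C_RspaMet = 0.6
C_RllaMet = 1.5
C_RrlaMet = 1.5
C_RubvMet = 0.046
C_RkidvMet = 0.06
C_RspvMet = 0.036
C_RllvMet = 0.12
C_RrlvMet = 0.12
C_O2ubvRef = 12.0
C_O2kidvRef = 15.5
C_O2spvRef = 13.0
C_O2llvRef = 12.0
C_O2rlvRef = 12.0
k_MET = 1.8
S0 = 0.27
T_Met = 2.0
T_Elmax = 8.0
T_Ermax = 8.0
T_Ris = 6.0
T_TCs = 2.0
T_TCv = 1.5
T_Vis = 20.0
VO2RR_int = 201.06
VO2RR_slope = 2.76
VO2leg_int = 28.87
VO2leg_slope = 3.83
RQ_int = 0.877
RQ_slope = 0.006
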