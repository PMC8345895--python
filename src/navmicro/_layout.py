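"""Fixed index layouts shared by the parameter packer and the numba kernels."""

# --- parameter vector -------------------------------------------------------
P_GAMMA_E = 0
P_GAMMA_I = 1
P_FRAC_E = 2       # Vol_e / Vol_o
P_FRAC_I = 3       # Vol_i / Vol_o
P_NA_SUM = 4
P_CL_SUM = 5
P_H1 = 6
P_H2 = 7
P_RTF = 8          # R*T/F in mV
P_CM = 9
P_RHO_PUMP = 10    # maximal pump rate at -70 mV
P_K_PUMP_NA = 11
P_K_PUMP_K = 12
P_PUMP_A = 13
P_PUMP_B = 14
P_PUMP_F70 = 15    # f(-70), precomputed normalisation
P_EPS_K = 16
P_K_BATH = 17
P_EPS_NA = 18      # 0 disables sodium bath exchange
P_NA_BATH = 19
P_G_NA_FI_E = 20
P_G_K_DR_E = 21
P_G_K_AHP_E = 22
P_K_CA = 23
P_G_NA_L_E = 24
P_G_K_L_E = 25
P_G_CL_L_E = 26
P_RHO_KCC = 27
P_RHO_NKCC = 28
P_K_NKCC_K = 29
P_G_GLU_E = 30
P_G_GABA_E = 31
P_G_D_E = 32
P_G_CA_E = 33
P_E_CA_E = 34
P_TAU_CA = 35
P_TAU_E = 36
P_V_THRES_E = 37
P_G_NA_FI_I = 38
P_G_NA_P_I = 39
P_G_K_DR_I = 40
P_G_NA_L_I = 41
P_G_K_L_I = 42
P_G_GLU_I = 43
P_G_D_I = 44
P_TAU_I = 45
P_V_THRES_I = 46
P_NA_P_SHIFT = 47  # leftward activation shift of the persistent current (mV)
P_PUMP_SCALE_E = 48  # pyramidal pump density relative to the interneuron's
N_PARAMS = 49

# --- reduced state (14 integrated variables) --------------------------------
R_V_E = 0
R_M_E = 1
R_H_E = 2
R_N_E = 3
R_NA_E = 4
R_CL_E = 5
R_CA_E = 6
R_S_E = 7
R_V_I = 8
R_H_I = 9
R_N_I = 10
R_NA_I = 11
R_S_I = 12
R_K_O = 13
N_REDUCED = 14

REDUCED_NAMES = (
    "v_e", "m_e", "h_e", "n_e", "Na_e", "Cl_e", "Ca_e", "s_e",
    "v_i", "h_i", "n_i", "Na_i", "s_i", "K_o",
)

# --- full state (18 variables): reduced layout plus the four derived ones ---
F_K_E = 14
F_K_I = 15
F_NA_O = 16
F_CL_O = 17
N_FULL = 18

FULL_NAMES = REDUCED_NAMES + ("K_e", "K_i", "Na_o", "Cl_o")

# --- isolated-interneuron state (6 variables) -------------------------------
I_V_I = 0
I_H_I = 1
I_N_I = 2
I_NA_I = 3
I_S_I = 4
I_K_O = 5
N_ISOLATED = 6

ISOLATED_NAMES = ("v_i", "h_i", "n_i", "Na_i", "s_i", "K_o")
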