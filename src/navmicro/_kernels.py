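"""Numba-compiled right-hand sides and fixed-step RK4 drivers.

The scalar kernels here mirror the numpy definitions in ``currents``/
``model`` (the test suite asserts bitwise-level agreement at random
states).  The drivers implement classical RK4 with spike-event handling:
after each accepted step, an upward crossing of the spike threshold sets
the corresponding synaptic variable to 1 and logs the crossing time by
linear interpolation.

Driver status codes: 0 = completed, 1 = non-finite state encountered,
2 = non-positive concentration encountered.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._layout import (  # noqa: F401
    P_GAMMA_E, P_GAMMA_I, P_FRAC_E, P_FRAC_I, P_NA_SUM, P_CL_SUM, P_H1, P_H2,
    P_RTF, P_CM, P_RHO_PUMP, P_K_PUMP_NA, P_K_PUMP_K, P_PUMP_A, P_PUMP_B,
    P_PUMP_F70, P_EPS_K, P_K_BATH, P_EPS_NA, P_NA_BATH, P_G_NA_FI_E,
    P_G_K_DR_E, P_G_K_AHP_E, P_K_CA, P_G_NA_L_E, P_G_K_L_E, P_G_CL_L_E,
    P_RHO_KCC, P_RHO_NKCC, P_K_NKCC_K, P_G_GLU_E, P_G_GABA_E, P_G_D_E,
    P_G_CA_E, P_E_CA_E, P_TAU_CA, P_TAU_E, P_V_THRES_E, P_G_NA_FI_I,
    P_G_NA_P_I, P_G_K_DR_I, P_G_NA_L_I, P_G_K_L_I, P_G_GLU_I, P_G_D_I,
    P_TAU_I, P_V_THRES_I, P_NA_P_SHIFT, P_PUMP_SCALE_E,
    R_V_E, R_M_E, R_H_E, R_N_E, R_NA_E, R_CL_E, R_CA_E, R_S_E, R_V_I, R_H_I,
    R_N_I, R_NA_I, R_S_I, R_K_O, N_REDUCED,
    F_K_E, F_K_I, F_NA_O, F_CL_O, N_FULL,
    I_V_I, I_H_I, I_N_I, I_NA_I, I_S_I, I_K_O, N_ISOLATED,
)


@njit(cache=True)
def _pump(v, na_in, k_o, p):
    f = 0.5 * (1.0 + math.tanh(p[P_PUMP_A] * v / p[P_RTF] + p[P_PUMP_B]))
    hill_na = na_in / (na_in + p[P_K_PUMP_NA])
    hill_k = k_o / (k_o + p[P_K_PUMP_K])
    return (p[P_RHO_PUMP] * f / p[P_PUMP_F70]
            * hill_na * hill_na * hill_na * hill_k * hill_k)


@njit(cache=True)
def _m_inf_i(v):
    return 1.0 / (1.0 + math.exp(-(v + 24.0) / 11.5))


@njit(cache=True)
def _pyr_net_currents(v, m, h, n, na_e, cl_e, ca, s_e, s_i,
                      k_e, k_o, na_o, cl_o, p):
    """Net (I_Na, I_K, I_Cl, I_Ca) of the pyramidal membrane."""
    rtf = p[P_RTF]
    e_na = rtf * math.log(na_o / na_e)
    e_k = rtf * math.log(k_o / k_e)
    e_cl = -rtf * math.log(cl_o / cl_e)

    i_na_fi = p[P_G_NA_FI_E] * m * m * m * h * (v - e_na)
    i_k_dr = p[P_G_K_DR_E] * n * n * n * n * (v - e_k)
    i_k_ahp = p[P_G_K_AHP_E] * ca / (ca + p[P_K_CA]) * (v - e_k)
    i_na_l = p[P_G_NA_L_E] * (v - e_na)
    i_k_l = p[P_G_K_L_E] * (v - e_k)
    i_cl_l = p[P_G_CL_L_E] * (v - e_cl)

    log_kcl = math.log(k_e * cl_e / (k_o * cl_o))
    log_nacl = math.log(na_e * cl_e / (na_o * cl_o))
    i_kcc = p[P_RHO_KCC] / p[P_GAMMA_E] * log_kcl
    i_nkcc = (p[P_RHO_NKCC] / p[P_GAMMA_E]
              / (1.0 + math.exp(p[P_K_NKCC_K] - k_o)) * (log_kcl + log_nacl))

    i_pump = p[P_PUMP_SCALE_E] * _pump(v, na_e, k_o, p)
    i_na_glu = 0.5 * p[P_G_GLU_E] * s_e * (v - e_na)
    i_k_glu = 0.5 * p[P_G_GLU_E] * s_e * (v - e_k)
    i_na_d = 0.5 * p[P_G_D_E] * (v - e_na)
    i_k_d = 0.5 * p[P_G_D_E] * (v - e_k)
    i_gaba = p[P_G_GABA_E] * s_i * (v - e_cl)

    m_ca = 1.0 / (1.0 + math.exp(-(v + 25.0) / 2.5))
    i_ca = p[P_G_CA_E] * m_ca * (v - p[P_E_CA_E])

    i_na = i_na_fi + i_na_l + 3.0 * i_pump + i_nkcc + i_na_glu + i_na_d
    i_k = (i_k_dr + i_k_ahp + i_k_l + i_kcc + i_nkcc - 2.0 * i_pump
           + i_k_glu + i_k_d)
    i_cl = i_cl_l - i_kcc - 2.0 * i_nkcc + i_gaba
    return i_na, i_k, i_cl, i_ca


@njit(cache=True)
def _int_net_currents(v, h, n, na_i, s_e, k_i, k_o, na_o, p):
    """Net (I_Na, I_K) of the interneuron membrane."""
    rtf = p[P_RTF]
    e_na = rtf * math.log(na_o / na_i)
    e_k = rtf * math.log(k_o / k_i)

    m_inf = _m_inf_i(v)
    i_na_fi = p[P_G_NA_FI_I] * m_inf * m_inf * m_inf * h * (v - e_na)
    m_p = _m_inf_i(v + p[P_NA_P_SHIFT])
    i_na_p = p[P_G_NA_P_I] * m_p * m_p * m_p * (v - e_na)
    i_k_dr = p[P_G_K_DR_I] * n * n * (v - e_k)
    i_na_l = p[P_G_NA_L_I] * (v - e_na)
    i_k_l = p[P_G_K_L_I] * (v - e_k)
    i_pump = _pump(v, na_i, k_o, p)
    i_na_glu = 0.5 * p[P_G_GLU_I] * s_e * (v - e_na)
    i_k_glu = 0.5 * p[P_G_GLU_I] * s_e * (v - e_k)
    i_na_d = 0.5 * p[P_G_D_I] * (v - e_na)
    i_k_d = 0.5 * p[P_G_D_I] * (v - e_k)

    i_na = i_na_fi + i_na_p + i_na_l + 3.0 * i_pump + i_na_glu + i_na_d
    i_k = i_k_dr + i_k_l - 2.0 * i_pump + i_k_glu + i_k_d
    return i_na, i_k


@njit(cache=True)
def _pyr_gating(v):
    x = v + 54.0
    am = 1.28 if abs(x) < 1e-7 else 0.32 * x / (1.0 - math.exp(-x / 4.0))
    x = v + 27.0
    bm = 1.4 if abs(x) < 1e-7 else 0.28 * x / (math.exp(x / 5.0) - 1.0)
    ah = 0.128 * math.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(v + 27.0) / 5.0))
    x = v + 52.0
    an = 0.16 if abs(x) < 1e-7 else 0.032 * x / (1.0 - math.exp(-x / 5.0))
    bn = 0.5 * math.exp(-(v + 57.0) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _int_gating(v):
    h_inf = 1.0 / (1.0 + math.exp((v + 58.3) / 6.7))
    tau_h = 0.5 + 14.0 / (1.0 + math.exp((v + 60.0) / 12.0))
    n_inf = 1.0 / (1.0 + math.exp(-(v + 12.4) / 6.8))
    tau_n = ((0.087 + 11.4 / (1.0 + math.exp((v + 14.6) / 8.6)))
             * (0.087 + 11.4 / (1.0 + math.exp(-(v - 1.3) / 18.7))))
    return h_inf, tau_h, n_inf, tau_n


@njit(cache=True)
def rhs_reduced(y, p, dy):
    v_e = y[R_V_E]
    v_i = y[R_V_I]
    na_e = y[R_NA_E]
    cl_e = y[R_CL_E]
    na_i = y[R_NA_I]
    k_o = y[R_K_O]
    cm = p[P_CM]

    k_e = p[P_GAMMA_E] * (cm * v_e - p[P_H1]) - na_e + cl_e
    k_i = p[P_GAMMA_I] * (cm * v_i - p[P_H2]) - na_i
    na_o = p[P_NA_SUM] - p[P_FRAC_E] * na_e - p[P_FRAC_I] * na_i
    cl_o = p[P_CL_SUM] - p[P_FRAC_E] * cl_e

    i_na_e, i_k_e, i_cl_e, i_ca = _pyr_net_currents(
        v_e, y[R_M_E], y[R_H_E], y[R_N_E], na_e, cl_e, y[R_CA_E],
        y[R_S_E], y[R_S_I], k_e, k_o, na_o, cl_o, p)
    i_na_i, i_k_i = _int_net_currents(
        v_i, y[R_H_I], y[R_N_I], na_i, y[R_S_E], k_i, k_o, na_o, p)

    am, bm, ah, bh, an, bn = _pyr_gating(v_e)
    h_inf, tau_h, n_inf, tau_n = _int_gating(v_i)

    dy[R_V_E] = (-i_na_e - i_k_e - i_cl_e) / cm
    dy[R_M_E] = am * (1.0 - y[R_M_E]) - bm * y[R_M_E]
    dy[R_H_E] = ah * (1.0 - y[R_H_E]) - bh * y[R_H_E]
    dy[R_N_E] = an * (1.0 - y[R_N_E]) - bn * y[R_N_E]
    dy[R_NA_E] = -p[P_GAMMA_E] * i_na_e
    dy[R_CL_E] = p[P_GAMMA_E] * i_cl_e
    dy[R_CA_E] = -0.5 * p[P_GAMMA_E] * i_ca - y[R_CA_E] / p[P_TAU_CA]
    dy[R_S_E] = -y[R_S_E] / p[P_TAU_E]
    dy[R_V_I] = (-i_na_i - i_k_i) / cm
    dy[R_H_I] = (h_inf - y[R_H_I]) / tau_h
    dy[R_N_I] = (n_inf - y[R_N_I]) / tau_n
    dy[R_NA_I] = -p[P_GAMMA_I] * i_na_i
    dy[R_S_I] = -y[R_S_I] / p[P_TAU_I]
    dy[R_K_O] = (p[P_FRAC_E] * p[P_GAMMA_E] * i_k_e
                 + p[P_FRAC_I] * p[P_GAMMA_I] * i_k_i
                 - p[P_EPS_K] * (k_o - p[P_K_BATH]))


@njit(cache=True)
def rhs_full(y, p, dy):
    v_e = y[R_V_E]
    v_i = y[R_V_I]
    na_e = y[R_NA_E]
    cl_e = y[R_CL_E]
    na_i = y[R_NA_I]
    k_o = y[R_K_O]
    k_e = y[F_K_E]
    k_i = y[F_K_I]
    na_o = y[F_NA_O]
    cl_o = y[F_CL_O]
    cm = p[P_CM]

    i_na_e, i_k_e, i_cl_e, i_ca = _pyr_net_currents(
        v_e, y[R_M_E], y[R_H_E], y[R_N_E], na_e, cl_e, y[R_CA_E],
        y[R_S_E], y[R_S_I], k_e, k_o, na_o, cl_o, p)
    i_na_i, i_k_i = _int_net_currents(
        v_i, y[R_H_I], y[R_N_I], na_i, y[R_S_E], k_i, k_o, na_o, p)

    am, bm, ah, bh, an, bn = _pyr_gating(v_e)
    h_inf, tau_h, n_inf, tau_n = _int_gating(v_i)

    dy[R_V_E] = (-i_na_e - i_k_e - i_cl_e) / cm
    dy[R_M_E] = am * (1.0 - y[R_M_E]) - bm * y[R_M_E]
    dy[R_H_E] = ah * (1.0 - y[R_H_E]) - bh * y[R_H_E]
    dy[R_N_E] = an * (1.0 - y[R_N_E]) - bn * y[R_N_E]
    dy[R_NA_E] = -p[P_GAMMA_E] * i_na_e
    dy[R_CL_E] = p[P_GAMMA_E] * i_cl_e
    dy[R_CA_E] = -0.5 * p[P_GAMMA_E] * i_ca - y[R_CA_E] / p[P_TAU_CA]
    dy[R_S_E] = -y[R_S_E] / p[P_TAU_E]
    dy[R_V_I] = (-i_na_i - i_k_i) / cm
    dy[R_H_I] = (h_inf - y[R_H_I]) / tau_h
    dy[R_N_I] = (n_inf - y[R_N_I]) / tau_n
    dy[R_NA_I] = -p[P_GAMMA_I] * i_na_i
    dy[R_S_I] = -y[R_S_I] / p[P_TAU_I]
    dy[R_K_O] = (p[P_FRAC_E] * p[P_GAMMA_E] * i_k_e
                 + p[P_FRAC_I] * p[P_GAMMA_I] * i_k_i
                 - p[P_EPS_K] * (k_o - p[P_K_BATH]))
    dy[F_K_E] = -p[P_GAMMA_E] * i_k_e
    dy[F_K_I] = -p[P_GAMMA_I] * i_k_i
    dy[F_NA_O] = (p[P_FRAC_E] * p[P_GAMMA_E] * i_na_e
                  + p[P_FRAC_I] * p[P_GAMMA_I] * i_na_i)
    if p[P_EPS_NA] > 0.0:
        dy[F_NA_O] -= p[P_EPS_NA] * (na_o - p[P_NA_BATH])
    dy[F_CL_O] = -p[P_FRAC_E] * p[P_GAMMA_E] * i_cl_e


@njit(cache=True)
def rhs_isolated(y, p, na_e_rest, dy):
    """Interneuron with the pyramidal cell frozen at rest: pyramidal
    contributions dropped from the extracellular potassium equation,
    [Na+]_o derived with [Na+]_e fixed, no glutamatergic input from the
    pyramidal cell (external drive only)."""
    v_i = y[I_V_I]
    na_i = y[I_NA_I]
    k_o = y[I_K_O]
    cm = p[P_CM]

    k_i = p[P_GAMMA_I] * (cm * v_i - p[P_H2]) - na_i
    na_o = p[P_NA_SUM] - p[P_FRAC_E] * na_e_rest - p[P_FRAC_I] * na_i

    i_na_i, i_k_i = _int_net_currents(
        v_i, y[I_H_I], y[I_N_I], na_i, 0.0, k_i, k_o, na_o, p)

    h_inf, tau_h, n_inf, tau_n = _int_gating(v_i)
    dy[I_V_I] = (-i_na_i - i_k_i) / cm
    dy[I_H_I] = (h_inf - y[I_H_I]) / tau_h
    dy[I_N_I] = (n_inf - y[I_N_I]) / tau_n
    dy[I_NA_I] = -p[P_GAMMA_I] * i_na_i
    dy[I_S_I] = -y[I_S_I] / p[P_TAU_I]
    dy[I_K_O] = (p[P_FRAC_I] * p[P_GAMMA_I] * i_k_i
                 - p[P_EPS_K] * (k_o - p[P_K_BATH]))


@njit(cache=True)
def rhs_fast(y, p, na_i, k_o, na_o):
    """Fast subsystem (v_i, h_i, n_i) with [Na+]_i clamped and frozen
    extracellular context; [K+]_i is derived from the H2 integral at the
    instantaneous voltage.  No synaptic variables (isolated interneuron)."""
    v_i = y[0]
    cm = p[P_CM]
    k_i = p[P_GAMMA_I] * (cm * v_i - p[P_H2]) - na_i
    i_na_i, i_k_i = _int_net_currents(
        v_i, y[1], y[2], na_i, 0.0, k_i, k_o, na_o, p)
    h_inf, tau_h, n_inf, tau_n = _int_gating(v_i)
    dv = (-i_na_i - i_k_i) / cm
    dh = (h_inf - y[1]) / tau_h
    dn = (n_inf - y[2]) / tau_n
    return dv, dh, dn


@njit(cache=True)
def _reduced_concentrations_ok(y, p):
    k_e = p[P_GAMMA_E] * (p[P_CM] * y[R_V_E] - p[P_H1]) - y[R_NA_E] + y[R_CL_E]
    k_i = p[P_GAMMA_I] * (p[P_CM] * y[R_V_I] - p[P_H2]) - y[R_NA_I]
    na_o = p[P_NA_SUM] - p[P_FRAC_E] * y[R_NA_E] - p[P_FRAC_I] * y[R_NA_I]
    cl_o = p[P_CL_SUM] - p[P_FRAC_E] * y[R_CL_E]
    return (k_e > 0.0 and k_i > 0.0 and na_o > 0.0 and cl_o > 0.0
            and y[R_NA_E] > 0.0 and y[R_CL_E] > 0.0 and y[R_NA_I] > 0.0
            and y[R_K_O] > 0.0)


@njit(cache=True)
def integrate_reduced(y0, p, dt, n_steps, stride):
    """RK4 with spike-event synaptic resets on the reduced system.

    Returns ``(status, t_last, Y, n_rec, spk_e, n_spk_e, spk_i, n_spk_i)``
    where ``Y[k]`` is the state after ``k*stride`` steps.
    """
    n = N_REDUCED
    n_rec = n_steps // stride + 1
    Y = np.empty((n_rec, n))
    max_spk = n_steps // 2 + 2
    spk_e = np.empty(max_spk)
    spk_i = np.empty(max_spk)
    n_spk_e = 0
    n_spk_i = 0

    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    Y[0] = y
    rec = 1
    status = 0
    t_last = 0.0
    thr_e = p[P_V_THRES_E]
    thr_i = p[P_V_THRES_I]

    for step in range(n_steps):
        t = step * dt
        v_e_prev = y[R_V_E]
        v_i_prev = y[R_V_I]

        rhs_reduced(y, p, k1)
        for j in range(n):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        rhs_reduced(yt, p, k2)
        for j in range(n):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        rhs_reduced(yt, p, k3)
        for j in range(n):
            yt[j] = y[j] + dt * k3[j]
        rhs_reduced(yt, p, k4)
        for j in range(n):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        if not (y[R_V_E] == y[R_V_E] and y[R_V_I] == y[R_V_I]):
            status = 1
            t_last = t
            break
        if not _reduced_concentrations_ok(y, p):
            status = 2
            t_last = t
            break

        if v_e_prev < thr_e and y[R_V_E] >= thr_e:
            y[R_S_E] = 1.0
            spk_e[n_spk_e] = t + dt * (thr_e - v_e_prev) / (y[R_V_E] - v_e_prev)
            n_spk_e += 1
        if v_i_prev < thr_i and y[R_V_I] >= thr_i:
            y[R_S_I] = 1.0
            spk_i[n_spk_i] = t + dt * (thr_i - v_i_prev) / (y[R_V_I] - v_i_prev)
            n_spk_i += 1

        if (step + 1) % stride == 0:
            Y[rec] = y
            rec += 1
        t_last = t + dt

    return status, t_last, Y, rec, spk_e, n_spk_e, spk_i, n_spk_i


@njit(cache=True)
def integrate_full(y0, p, dt, n_steps, stride):
    """RK4 with spike-event resets on the full 18-variable system."""
    n = N_FULL
    n_rec = n_steps // stride + 1
    Y = np.empty((n_rec, n))
    max_spk = n_steps // 2 + 2
    spk_e = np.empty(max_spk)
    spk_i = np.empty(max_spk)
    n_spk_e = 0
    n_spk_i = 0

    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    Y[0] = y
    rec = 1
    status = 0
    t_last = 0.0
    thr_e = p[P_V_THRES_E]
    thr_i = p[P_V_THRES_I]

    for step in range(n_steps):
        t = step * dt
        v_e_prev = y[R_V_E]
        v_i_prev = y[R_V_I]

        rhs_full(y, p, k1)
        for j in range(n):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        rhs_full(yt, p, k2)
        for j in range(n):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        rhs_full(yt, p, k3)
        for j in range(n):
            yt[j] = y[j] + dt * k3[j]
        rhs_full(yt, p, k4)
        for j in range(n):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        if not (y[R_V_E] == y[R_V_E] and y[R_V_I] == y[R_V_I]):
            status = 1
            t_last = t
            break
        if (y[F_K_E] <= 0.0 or y[F_K_I] <= 0.0 or y[F_NA_O] <= 0.0
                or y[F_CL_O] <= 0.0 or y[R_NA_E] <= 0.0 or y[R_CL_E] <= 0.0
                or y[R_NA_I] <= 0.0 or y[R_K_O] <= 0.0):
            status = 2
            t_last = t
            break

        if v_e_prev < thr_e and y[R_V_E] >= thr_e:
            y[R_S_E] = 1.0
            spk_e[n_spk_e] = t + dt * (thr_e - v_e_prev) / (y[R_V_E] - v_e_prev)
            n_spk_e += 1
        if v_i_prev < thr_i and y[R_V_I] >= thr_i:
            y[R_S_I] = 1.0
            spk_i[n_spk_i] = t + dt * (thr_i - v_i_prev) / (y[R_V_I] - v_i_prev)
            n_spk_i += 1

        if (step + 1) % stride == 0:
            Y[rec] = y
            rec += 1
        t_last = t + dt

    return status, t_last, Y, rec, spk_e, n_spk_e, spk_i, n_spk_i


@njit(cache=True)
def integrate_isolated(y0, p, na_e_rest, dt, n_steps, stride):
    """RK4 on the isolated-interneuron system."""
    n = N_ISOLATED
    n_rec = n_steps // stride + 1
    Y = np.empty((n_rec, n))
    max_spk = n_steps // 2 + 2
    spk_i = np.empty(max_spk)
    n_spk_i = 0

    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    Y[0] = y
    rec = 1
    status = 0
    t_last = 0.0
    thr_i = p[P_V_THRES_I]

    for step in range(n_steps):
        t = step * dt
        v_i_prev = y[I_V_I]

        rhs_isolated(y, p, na_e_rest, k1)
        for j in range(n):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        rhs_isolated(yt, p, na_e_rest, k2)
        for j in range(n):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        rhs_isolated(yt, p, na_e_rest, k3)
        for j in range(n):
            yt[j] = y[j] + dt * k3[j]
        rhs_isolated(yt, p, na_e_rest, k4)
        for j in range(n):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        if not (y[I_V_I] == y[I_V_I]):
            status = 1
            t_last = t
            break
        k_i = p[P_GAMMA_I] * (p[P_CM] * y[I_V_I] - p[P_H2]) - y[I_NA_I]
        na_o = p[P_NA_SUM] - p[P_FRAC_E] * na_e_rest - p[P_FRAC_I] * y[I_NA_I]
        if k_i <= 0.0 or na_o <= 0.0 or y[I_NA_I] <= 0.0 or y[I_K_O] <= 0.0:
            status = 2
            t_last = t
            break

        if v_i_prev < thr_i and y[I_V_I] >= thr_i:
            y[I_S_I] = 1.0
            spk_i[n_spk_i] = t + dt * (thr_i - v_i_prev) / (y[I_V_I] - v_i_prev)
            n_spk_i += 1

        if (step + 1) % stride == 0:
            Y[rec] = y
            rec += 1
        t_last = t + dt

    return status, t_last, Y, rec, spk_i, n_spk_i


@njit(cache=True)
def integrate_fast(y0, p, na_i, k_o, na_o, dt, n_steps, stride):
    """Plain RK4 on the three-variable fast subsystem (no events)."""
    n_rec = n_steps // stride + 1
    Y = np.empty((n_rec, 3))
    v, h, nn = y0[0], y0[1], y0[2]
    Y[0, 0] = v
    Y[0, 1] = h
    Y[0, 2] = nn
    rec = 1
    y = np.empty(3)
    y[0], y[1], y[2] = v, h, nn
    for step in range(n_steps):
        dv1, dh1, dn1 = rhs_fast(y, p, na_i, k_o, na_o)
        yt = np.empty(3)
        yt[0] = y[0] + 0.5 * dt * dv1
        yt[1] = y[1] + 0.5 * dt * dh1
        yt[2] = y[2] + 0.5 * dt * dn1
        dv2, dh2, dn2 = rhs_fast(yt, p, na_i, k_o, na_o)
        yt[0] = y[0] + 0.5 * dt * dv2
        yt[1] = y[1] + 0.5 * dt * dh2
        yt[2] = y[2] + 0.5 * dt * dn2
        dv3, dh3, dn3 = rhs_fast(yt, p, na_i, k_o, na_o)
        yt[0] = y[0] + dt * dv3
        yt[1] = y[1] + dt * dh3
        yt[2] = y[2] + dt * dn3
        dv4, dh4, dn4 = rhs_fast(yt, p, na_i, k_o, na_o)
        y[0] += dt / 6.0 * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
        y[1] += dt / 6.0 * (dh1 + 2.0 * dh2 + 2.0 * dh3 + dh4)
        y[2] += dt / 6.0 * (dn1 + 2.0 * dn2 + 2.0 * dn3 + dn4)
        if (step + 1) % stride == 0:
            Y[rec, 0] = y[0]
            Y[rec, 1] = y[1]
            Y[rec, 2] = y[2]
            rec += 1
    return Y, rec
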