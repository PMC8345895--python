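"""Right-hand sides of the full (18-variable) and reduced (14-variable)
ODE systems, in plain numpy.

These are the reference definitions used for analysis and testing; the
fixed-step integrator uses the compiled kernels in ``_kernels``, which are
checked against these functions.

Synaptic resets (s <- 1 on an upward spike-threshold crossing) are event
actions handled by the integrator, not part of the vector field.
"""

from __future__ import annotations

import numpy as np

from . import _layout as L
from .currents import (interneuron_currents, pyramidal_currents,
                       pyramidal_gating_rates, interneuron_gating)
from .parameters import ModelParameters
from .states import FullState, ReducedState


def _derivatives(params: ModelParameters, fs: FullState):
    """Common core: per-mechanism currents and the 14 reduced derivatives."""
    pc = pyramidal_currents(
        params, v_e=fs.v_e, m_e=fs.m_e, h_e=fs.h_e, n_e=fs.n_e,
        K_e=fs.K_e, Na_e=fs.Na_e, Cl_e=fs.Cl_e, Ca_e=fs.Ca_e,
        s_e=fs.s_e, s_i=fs.s_i, K_o=fs.K_o, Na_o=fs.Na_o, Cl_o=fs.Cl_o)
    ic = interneuron_currents(
        params, v_i=fs.v_i, h_i=fs.h_i, n_i=fs.n_i, K_i=fs.K_i,
        Na_i=fs.Na_i, s_e=fs.s_e, K_o=fs.K_o, Na_o=fs.Na_o)

    c = params.constants
    g = params.geometry
    py, it, ba = params.pyramidal, params.interneuron, params.bath

    am, bm, ah, bh, an, bn = pyramidal_gating_rates(fs.v_e)
    _, h_inf, tau_h, n_inf, tau_n = interneuron_gating(fs.v_i)

    dy = np.empty(L.N_REDUCED)
    dy[L.R_V_E] = (-pc.I_Na_e - pc.I_K_e - pc.I_Cl_e) / c.C_m
    dy[L.R_M_E] = am * (1.0 - fs.m_e) - bm * fs.m_e
    dy[L.R_H_E] = ah * (1.0 - fs.h_e) - bh * fs.h_e
    dy[L.R_N_E] = an * (1.0 - fs.n_e) - bn * fs.n_e
    dy[L.R_NA_E] = -g.gamma_e * pc.I_Na_e
    dy[L.R_CL_E] = g.gamma_e * pc.I_Cl_e
    dy[L.R_CA_E] = -g.gamma_e / 2.0 * pc.I_Ca_e - fs.Ca_e / py.tau_Ca
    dy[L.R_S_E] = -fs.s_e / py.tau_e
    dy[L.R_V_I] = (-ic.I_Na_i - ic.I_K_i) / c.C_m
    dy[L.R_H_I] = (h_inf - fs.h_i) / tau_h
    dy[L.R_N_I] = (n_inf - fs.n_i) / tau_n
    dy[L.R_NA_I] = -g.gamma_i * ic.I_Na_i
    dy[L.R_S_I] = -fs.s_i / it.tau_i
    dy[L.R_K_O] = (g.vol_frac_e * g.gamma_e * pc.I_K_e
                   + g.vol_frac_i * g.gamma_i * ic.I_K_i
                   - ba.eps_K * (fs.K_o - ba.K_bath))
    return dy, pc, ic


def rhs_reduced(state, params: ModelParameters) -> np.ndarray:
    """Time derivative of the 14 reduced variables."""
    if not isinstance(state, ReducedState):
        state = ReducedState.from_array(np.asarray(state, dtype=float))
    dy, _, _ = _derivatives(params, state.lift(params))
    return dy


def rhs_full(state, params: ModelParameters) -> np.ndarray:
    """Time derivative of all 18 variables.

    The extracellular sodium and chloride equations carry no diffusion
    term unless a sodium bath exchange is enabled (``bath.eps_Na > 0``),
    which deliberately breaks sodium mass conservation.
    """
    if not isinstance(state, FullState):
        state = FullState.from_array(np.asarray(state, dtype=float))
    dy14, pc, ic = _derivatives(params, state)
    g, ba = params.geometry, params.bath
    dy = np.empty(L.N_FULL)
    dy[: L.N_REDUCED] = dy14
    dy[L.F_K_E] = -g.gamma_e * pc.I_K_e
    dy[L.F_K_I] = -g.gamma_i * ic.I_K_i
    dy[L.F_NA_O] = (g.vol_frac_e * g.gamma_e * pc.I_Na_e
                    + g.vol_frac_i * g.gamma_i * ic.I_Na_i)
    if ba.eps_Na > 0.0:
        dy[L.F_NA_O] -= ba.eps_Na * (state.Na_o - ba.Na_bath)
    dy[L.F_CL_O] = -g.vol_frac_e * g.gamma_e * pc.I_Cl_e
    return dy
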