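"""Transmembrane currents, gating kinetics and the Na+/K+-ATPase.

All functions accept scalars or numpy arrays and return values in the
package unit system (mV, ms, mM, uA/cm^2).  Reversal potentials are
recomputed from the instantaneous ion concentrations via the Nernst
equation; only the calcium reversal is held fixed.

Sign conventions follow the usual Hodgkin-Huxley form: positive current is
outward and depletes the corresponding intracellular concentration.  The
pump moves 3 Na+ out per 2 K+ in, so it enters the net sodium current with
weight +3 and the net potassium current with weight -2.  NKCC1 (1Na:1K:2Cl
inward) enters the Na/K/Cl nets with weights +1/+1/-2 and KCC2 extrudes K
and Cl with +1/-1 weights.  Both cotransporters are electroneutral, so
their contributions cancel from the membrane-potential equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .parameters import ModelParameters, PumpParameters


class ConcentrationError(ValueError):
    """A concentration that must be positive was not."""


def _check_positive(name: str, value: Any) -> None:
    if np.any(np.asarray(value) <= 0.0):
        raise ConcentrationError(
            f"{name} must be positive, got {np.min(np.asarray(value))}")


def reversal_potential(z: int, c_out, c_in, RTF: float = 26.685) -> Any:
    """Nernst potential (mV) for an ion of valence ``z``.

    ``RTF`` is R*T/F in mV; the default corresponds to 309.15 K with the
    model's Faraday constant.
    """
    if z == 0:
        raise ValueError("ion valence must be nonzero")
    _check_positive("c_out", c_out)
    _check_positive("c_in", c_in)
    return (RTF / z) * np.log(np.asarray(c_out, dtype=float) / c_in)


def pump_rate(v, params: PumpParameters, RTF: float) -> Any:
    """Voltage-dependent maximal pump rate rho(v) (uA/cm^2).

    rho(v) = rho_{-70} * f(v)/f(-70) with f(v) = (1 + tanh(a*v/RTF + b))/2:
    the pump speeds up with depolarization.
    """
    f = 0.5 * (1.0 + np.tanh(params.a * np.asarray(v, dtype=float) / RTF + params.b))
    f70 = 0.5 * (1.0 + np.tanh(params.a * (-70.0) / RTF + params.b))
    return params.rho_pump_m70 * f / f70


def pump_current(v, Na_in, K_o, params: PumpParameters,
                 RTF: float = 26.685) -> Any:
    """Na+/K+-ATPase current (uA/cm^2), strictly increasing in v, Na_in, K_o."""
    _check_positive("Na_in", Na_in)
    _check_positive("K_o", K_o)
    na = np.asarray(Na_in, dtype=float)
    ko = np.asarray(K_o, dtype=float)
    return (pump_rate(v, params, RTF)
            * (na / (na + params.K_pump_Na)) ** 3
            * (ko / (ko + params.K_pump_K)) ** 2)


# --------------------------------------------------------------------------
# Gating kinetics
# --------------------------------------------------------------------------

def _ratefun(v, scale, shift, slope):
    """scale * x / (1 - exp(-x/slope)) with x = v + shift; the removable
    singularity at x = 0 is filled with the limit value scale*slope."""
    x = np.asarray(v, dtype=float) + shift
    small = np.abs(x) < 1e-7
    xs = np.where(small, 1.0, x)
    out = scale * xs / (1.0 - np.exp(-xs / slope))
    return np.where(small, scale * slope, out)


def pyramidal_gating_rates(v):
    """Traub-Miles style alpha/beta rates (1/ms) for m_e, h_e, n_e.

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)``.
    """
    v = np.asarray(v, dtype=float)
    alpha_m = _ratefun(v, 0.32, 54.0, 4.0)
    beta_m = _ratefun(-v, 0.28, -27.0, 5.0)  # 0.28(v+27)/(exp((v+27)/5)-1)
    alpha_h = 0.128 * np.exp(-(v + 50.0) / 18.0)
    beta_h = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    alpha_n = _ratefun(v, 0.032, 52.0, 5.0)
    beta_n = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def interneuron_gating(v):
    """Fast-spiking cortical interneuron kinetics (Golomb-type).

    Returns ``(m_inf, h_inf, tau_h, n_inf, tau_n)``.  ``m`` is
    instantaneous; ``h`` is an inactivation variable (decreasing sigmoid);
    ``tau_n`` is a product of two shifted sigmoids.
    """
    v = np.asarray(v, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(v + 24.0) / 11.5))
    h_inf = 1.0 / (1.0 + np.exp((v + 58.3) / 6.7))
    tau_h = 0.5 + 14.0 / (1.0 + np.exp((v + 60.0) / 12.0))
    n_inf = 1.0 / (1.0 + np.exp(-(v + 12.4) / 6.8))
    tau_n = ((0.087 + 11.4 / (1.0 + np.exp((v + 14.6) / 8.6)))
             * (0.087 + 11.4 / (1.0 + np.exp(-(v - 1.3) / 18.7))))
    return m_inf, h_inf, tau_h, n_inf, tau_n


def m_inf_Ca(v):
    """Instantaneous activation of the pyramidal high-threshold Ca2+ current."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) + 25.0) / 2.5))


# --------------------------------------------------------------------------
# Labelled current sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PyramidalCurrents:
    """Per-mechanism pyramidal currents (uA/cm^2) plus their reversals."""

    I_Na_FI_e: Any
    I_K_DR_e: Any
    I_K_AHP_e: Any
    I_Na_L_e: Any
    I_K_L_e: Any
    I_Cl_L_e: Any
    I_KCC: Any
    I_NKCC: Any
    I_Na_GLU_e: Any
    I_K_GLU_e: Any
    I_Na_D_e: Any
    I_K_D_e: Any
    I_GABA_e: Any
    I_pump_e: Any
    I_Ca_e: Any
    E_Na_e: Any
    E_K_e: Any
    E_Cl_e: Any

    @property
    def I_Na_e(self) -> Any:
        """Net sodium current of the voltage equation."""
        return (self.I_Na_FI_e + self.I_Na_L_e + 3.0 * self.I_pump_e
                + self.I_NKCC + self.I_Na_GLU_e + self.I_Na_D_e)

    @property
    def I_K_e(self) -> Any:
        return (self.I_K_DR_e + self.I_K_AHP_e + self.I_K_L_e + self.I_KCC
                + self.I_NKCC - 2.0 * self.I_pump_e + self.I_K_GLU_e
                + self.I_K_D_e)

    @property
    def I_Cl_e(self) -> Any:
        return self.I_Cl_L_e - self.I_KCC - 2.0 * self.I_NKCC + self.I_GABA_e


@dataclass(frozen=True)
class InterneuronCurrents:
    """Per-mechanism interneuron currents (uA/cm^2); no chloride pathway."""

    I_Na_FI_i: Any
    I_Na_P_i: Any
    I_K_DR_i: Any
    I_Na_L_i: Any
    I_K_L_i: Any
    I_Na_GLU_i: Any
    I_K_GLU_i: Any
    I_Na_D_i: Any
    I_K_D_i: Any
    I_pump_i: Any
    E_Na_i: Any
    E_K_i: Any

    @property
    def I_Na_i(self) -> Any:
        return (self.I_Na_FI_i + self.I_Na_P_i + self.I_Na_L_i
                + 3.0 * self.I_pump_i + self.I_Na_GLU_i + self.I_Na_D_i)

    @property
    def I_K_i(self) -> Any:
        return (self.I_K_DR_i + self.I_K_L_i - 2.0 * self.I_pump_i
                + self.I_K_GLU_i + self.I_K_D_i)


def pyramidal_currents(params: ModelParameters, *, v_e, m_e, h_e, n_e,
                       K_e, Na_e, Cl_e, Ca_e, s_e, s_i,
                       K_o, Na_o, Cl_o) -> PyramidalCurrents:
    """Evaluate every pyramidal membrane mechanism at the given state."""
    py, pu = params.pyramidal, params.pump
    RTF = params.constants.RTF
    gamma_e = params.geometry.gamma_e

    E_Na = reversal_potential(1, Na_o, Na_e, RTF)
    E_K = reversal_potential(1, K_o, K_e, RTF)
    E_Cl = reversal_potential(-1, Cl_o, Cl_e, RTF)

    _check_positive("[K]_e[Cl]_e", np.asarray(K_e) * np.asarray(Cl_e))
    ratio_KCl = (np.asarray(K_e, dtype=float) * Cl_e) / (np.asarray(K_o) * Cl_o)
    ratio_NaCl = (np.asarray(Na_e, dtype=float) * Cl_e) / (np.asarray(Na_o) * Cl_o)

    I_KCC = py.rho_KCC / gamma_e * np.log(ratio_KCl)
    I_NKCC = (py.rho_NKCC / gamma_e
              / (1.0 + np.exp(py.K_NKCC_K - np.asarray(K_o, dtype=float)))
              * (np.log(ratio_KCl) + np.log(ratio_NaCl)))
    return PyramidalCurrents(
        I_Na_FI_e=py.g_Na_FI_e * np.asarray(m_e) ** 3 * h_e * (v_e - E_Na),
        I_K_DR_e=py.g_K_DR_e * np.asarray(n_e) ** 4 * (v_e - E_K),
        I_K_AHP_e=py.g_K_AHP_e * np.asarray(Ca_e) / (np.asarray(Ca_e) + py.K_Ca)
        * (v_e - E_K),
        I_Na_L_e=py.g_Na_L_e * (v_e - E_Na),
        I_K_L_e=py.g_K_L_e * (v_e - E_K),
        I_Cl_L_e=py.g_Cl_L_e * (v_e - E_Cl),
        I_KCC=I_KCC,
        I_NKCC=I_NKCC,
        I_Na_GLU_e=0.5 * py.g_GLU_e * np.asarray(s_e) * (v_e - E_Na),
        I_K_GLU_e=0.5 * py.g_GLU_e * np.asarray(s_e) * (v_e - E_K),
        I_Na_D_e=0.5 * py.g_D_e * (np.asarray(v_e, dtype=float) - E_Na),
        I_K_D_e=0.5 * py.g_D_e * (np.asarray(v_e, dtype=float) - E_K),
        I_GABA_e=py.g_GABA_e * np.asarray(s_i) * (v_e - E_Cl),
        I_pump_e=pu.scale_e * pump_current(v_e, Na_e, K_o, pu, RTF),
        I_Ca_e=py.g_Ca_e * m_inf_Ca(v_e) * (np.asarray(v_e, dtype=float) - py.E_Ca_e),
        E_Na_e=E_Na, E_K_e=E_K, E_Cl_e=E_Cl,
    )


def interneuron_currents(params: ModelParameters, *, v_i, h_i, n_i,
                         K_i, Na_i, s_e, K_o, Na_o) -> InterneuronCurrents:
    """Evaluate every interneuron membrane mechanism at the given state.

    The persistent sodium current uses the activation sigmoid evaluated at
    ``v_i + shift`` (an 8 mV leftward shift of activation), cubed, with no
    inactivation factor.
    """
    it, pu = params.interneuron, params.pump
    RTF = params.constants.RTF

    E_Na = reversal_potential(1, Na_o, Na_i, RTF)
    E_K = reversal_potential(1, K_o, K_i, RTF)

    m_inf = interneuron_gating(v_i)[0]
    m_inf_shifted = interneuron_gating(np.asarray(v_i, dtype=float)
                                       + it.na_p_shift)[0]
    return InterneuronCurrents(
        I_Na_FI_i=it.g_Na_FI_i * m_inf ** 3 * h_i * (v_i - E_Na),
        I_Na_P_i=it.g_Na_P_i * m_inf_shifted ** 3
        * (np.asarray(v_i, dtype=float) - E_Na),
        I_K_DR_i=it.g_K_DR_i * np.asarray(n_i) ** 2 * (v_i - E_K),
        I_Na_L_i=it.g_Na_L_i * (v_i - E_Na),
        I_K_L_i=it.g_K_L_i * (v_i - E_K),
        I_Na_GLU_i=0.5 * it.g_GLU_i * np.asarray(s_e) * (v_i - E_Na),
        I_K_GLU_i=0.5 * it.g_GLU_i * np.asarray(s_e) * (v_i - E_K),
        I_Na_D_i=0.5 * it.g_D_i * (np.asarray(v_i, dtype=float) - E_Na),
        I_K_D_i=0.5 * it.g_D_i * (np.asarray(v_i, dtype=float) - E_K),
        I_pump_i=pump_current(v_i, Na_i, K_o, pu, RTF),
        E_Na_i=E_Na, E_K_i=E_K,
    )
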