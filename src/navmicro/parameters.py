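"""Model parameters, NaV1.1 mutation transforms and flat-file serialization.

All default values are the reference parameter set of the microcircuit model
(conductances in mS/cm^2, concentrations in mM, times in ms).  The NaV1.1
variants touch only the interneuron's voltage-gated sodium conductances:

* ``fhm3`` (gain of function, hemiplegic-migraine type 3): a fraction
  ``p_Na_P`` of the total sodium conductance (112.5 mS/cm^2, kept constant)
  is converted into a non-inactivating persistent current whose activation
  is shifted 8 mV towards more negative potentials.
* ``epileptogenic`` (loss of function, e.g. Dravet syndrome): the
  fast-inactivating conductance is scaled down (default to 40% of 112.5,
  i.e. 45 mS/cm^2), with no persistent current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import IO, Literal, Union

import numpy as np

from . import _layout as L
from .constants import ConservedTotals, Geometry, PhysicalConstants


@dataclass(frozen=True)
class PyramidalParameters:
    g_Na_FI_e: float = 100.0   # fast inactivating Na+ conductance
    g_K_DR_e: float = 80.0     # delayed rectifier K+
    g_K_AHP_e: float = 1.0     # Ca2+-activated K+ (afterhyperpolarization)
    K_Ca: float = 0.001        # half activation [Ca2+]_e of I_K_AHP (mM)
    g_Na_L_e: float = 0.015    # Na+ leak
    g_K_L_e: float = 0.05      # K+ leak
    g_Cl_L_e: float = 0.015    # Cl- leak
    rho_KCC: float = 0.0003    # KCC2 cotransporter strength (mM/ms)
    rho_NKCC: float = 0.0001   # NKCC1 cotransporter strength (mM/ms)
    K_NKCC_K: float = 16.0     # NKCC1 half activation [K+]_o (mM)
    g_GLU_e: float = 0.1       # glutamatergic autapse
    g_GABA_e: float = 2.5      # GABAergic synapse from the interneuron
    g_D_e: float = 0.0         # external glutamatergic drive
    g_Ca_e: float = 1.0        # high-threshold Ca2+ conductance
    E_Ca_e: float = 120.0      # fixed Ca2+ reversal (mV)
    tau_Ca: float = 80.0       # Ca2+ extrusion/buffering time constant (ms)
    tau_e: float = 3.0         # synaptic decay of s_e (ms)
    v_thres_e: float = 0.0     # spike threshold (mV)


@dataclass(frozen=True)
class InterneuronParameters:
    g_Na_FI_i: float = 112.5   # fast inactivating Na+ conductance
    g_Na_P_i: float = 0.0      # persistent Na+ conductance (FHM-3 variants)
    g_K_DR_i: float = 225.0    # delayed rectifier K+
    g_Na_L_i: float = 0.012    # Na+ leak
    g_K_L_i: float = 0.05      # K+ leak
    g_GLU_i: float = 0.1       # glutamatergic synapse from the pyramidal cell
    g_D_i: float = 0.0         # external glutamatergic drive
    tau_i: float = 9.0         # synaptic decay of s_i (ms)
    v_thres_i: float = 0.0     # spike threshold (mV)
    na_p_shift: float = 8.0    # activation shift of the persistent current (mV)


@dataclass(frozen=True)
class PumpParameters:
    """Na+/K+-ATPase: Hill factors in [Na+]_in and [K+]_o with a sigmoidal
    voltage dependence of the maximal rate, normalised to its value at
    -70 mV."""

    rho_pump_m70: float = 30.0  # maximal rate at -70 mV (uA/cm^2)
    K_pump_Na: float = 7.7      # half activation [Na+]_in (mM)
    K_pump_K: float = 2.0       # half activation [K+]_o (mM)
    a: float = 0.39             # voltage-dependence shape
    b: float = 1.28             # voltage-dependence offset
    scale_e: float = 1.0        # pyramidal pump density relative to rho_pump_m70


@dataclass(frozen=True)
class BathParameters:
    eps_K: float = 5e-4        # extracellular K+ diffusion/buffering rate (1/ms)
    K_bath: float = 3.5        # K+ bath concentration (mM)
    eps_Na: float = 0.0        # optional Na+ bath exchange rate (1/ms)
    Na_bath: float = 0.0       # Na+ bath value (mM), used when eps_Na > 0


TOTAL_G_NA_I = 112.5  # g_Na_FI_i + g_Na_P_i is held constant (mS/cm^2)


@dataclass(frozen=True)
class MutationSpec:
    """Declarative NaV1.1 variant description.

    ``wild_type``: identity.  ``fhm3``: ``p_Na_P`` percent of the total
    sodium conductance becomes persistent.  ``epileptogenic``:
    ``conductance_scale`` times the default fast-inactivating conductance.
    """

    variant: Literal["wild_type", "fhm3", "epileptogenic"] = "wild_type"
    p_Na_P: float = 0.0
    conductance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in ("wild_type", "fhm3", "epileptogenic"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "fhm3" and not 0.0 <= self.p_Na_P <= 100.0:
            raise ValueError(f"p_Na_P must be in [0, 100], got {self.p_Na_P}")
        if (self.variant == "epileptogenic"
                and not 0.0 < self.conductance_scale <= 1.0):
            raise ValueError(
                f"conductance_scale must be in (0, 1], got {self.conductance_scale}")

    @staticmethod
    def wild_type() -> "MutationSpec":
        return MutationSpec("wild_type")

    @staticmethod
    def fhm3(p_Na_P: float) -> "MutationSpec":
        return MutationSpec("fhm3", p_Na_P=p_Na_P)

    @staticmethod
    def epileptogenic(conductance_scale: float = 0.4) -> "MutationSpec":
        return MutationSpec("epileptogenic", conductance_scale=conductance_scale)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the microcircuit model."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    geometry: Geometry = field(default_factory=Geometry)
    pyramidal: PyramidalParameters = field(default_factory=PyramidalParameters)
    interneuron: InterneuronParameters = field(default_factory=InterneuronParameters)
    pump: PumpParameters = field(default_factory=PumpParameters)
    bath: BathParameters = field(default_factory=BathParameters)

    @property
    def totals(self) -> ConservedTotals:
        return ConservedTotals(self.geometry)

    # -- mutation transform --------------------------------------------------
    def with_mutation(self, spec: MutationSpec) -> "ModelParameters":
        """Return a parameter set with the NaV1.1 variant applied.

        Only ``g_Na_FI_i`` and ``g_Na_P_i`` are touched; the pyramidal
        neuron is unaffected.
        """
        if spec.variant == "wild_type":
            inter = replace(self.interneuron,
                            g_Na_FI_i=TOTAL_G_NA_I, g_Na_P_i=0.0)
        elif spec.variant == "fhm3":
            g_p = spec.p_Na_P / 100.0 * TOTAL_G_NA_I
            inter = replace(self.interneuron,
                            g_Na_FI_i=TOTAL_G_NA_I - g_p, g_Na_P_i=g_p)
        else:  # epileptogenic
            inter = replace(self.interneuron,
                            g_Na_FI_i=spec.conductance_scale * TOTAL_G_NA_I,
                            g_Na_P_i=0.0)
        return replace(self, interneuron=inter)

    def with_drives(self, g_D_e: float | None = None,
                    g_D_i: float | None = None) -> "ModelParameters":
        pyr = self.pyramidal if g_D_e is None else replace(self.pyramidal, g_D_e=g_D_e)
        inter = (self.interneuron if g_D_i is None
                 else replace(self.interneuron, g_D_i=g_D_i))
        return replace(self, pyramidal=pyr, interneuron=inter)

    # -- packing for the integration kernels ---------------------------------
    def to_array(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the numba kernels."""
        c, g, py, it, pu, ba = (self.constants, self.geometry, self.pyramidal,
                                self.interneuron, self.pump, self.bath)
        tot = self.totals
        p = np.empty(L.N_PARAMS, dtype=np.float64)
        p[L.P_GAMMA_E] = g.gamma_e
        p[L.P_GAMMA_I] = g.gamma_i
        p[L.P_FRAC_E] = g.vol_frac_e
        p[L.P_FRAC_I] = g.vol_frac_i
        p[L.P_NA_SUM] = tot.Na_sum
        p[L.P_CL_SUM] = tot.Cl_sum
        p[L.P_H1] = tot.H1
        p[L.P_H2] = tot.H2
        p[L.P_RTF] = c.RTF
        p[L.P_CM] = c.C_m
        p[L.P_RHO_PUMP] = pu.rho_pump_m70
        p[L.P_K_PUMP_NA] = pu.K_pump_Na
        p[L.P_K_PUMP_K] = pu.K_pump_K
        p[L.P_PUMP_A] = pu.a
        p[L.P_PUMP_B] = pu.b
        p[L.P_PUMP_F70] = 0.5 * (1.0 + math.tanh(pu.a * (-70.0) / c.RTF + pu.b))
        p[L.P_EPS_K] = ba.eps_K
        p[L.P_K_BATH] = ba.K_bath
        p[L.P_EPS_NA] = ba.eps_Na
        p[L.P_NA_BATH] = ba.Na_bath
        p[L.P_G_NA_FI_E] = py.g_Na_FI_e
        p[L.P_G_K_DR_E] = py.g_K_DR_e
        p[L.P_G_K_AHP_E] = py.g_K_AHP_e
        p[L.P_K_CA] = py.K_Ca
        p[L.P_G_NA_L_E] = py.g_Na_L_e
        p[L.P_G_K_L_E] = py.g_K_L_e
        p[L.P_G_CL_L_E] = py.g_Cl_L_e
        p[L.P_RHO_KCC] = py.rho_KCC
        p[L.P_RHO_NKCC] = py.rho_NKCC
        p[L.P_K_NKCC_K] = py.K_NKCC_K
        p[L.P_G_GLU_E] = py.g_GLU_e
        p[L.P_G_GABA_E] = py.g_GABA_e
        p[L.P_G_D_E] = py.g_D_e
        p[L.P_G_CA_E] = py.g_Ca_e
        p[L.P_E_CA_E] = py.E_Ca_e
        p[L.P_TAU_CA] = py.tau_Ca
        p[L.P_TAU_E] = py.tau_e
        p[L.P_V_THRES_E] = py.v_thres_e
        p[L.P_G_NA_FI_I] = it.g_Na_FI_i
        p[L.P_G_NA_P_I] = it.g_Na_P_i
        p[L.P_G_K_DR_I] = it.g_K_DR_i
        p[L.P_G_NA_L_I] = it.g_Na_L_i
        p[L.P_G_K_L_I] = it.g_K_L_i
        p[L.P_G_GLU_I] = it.g_GLU_i
        p[L.P_G_D_I] = it.g_D_i
        p[L.P_TAU_I] = it.tau_i
        p[L.P_V_THRES_I] = it.v_thres_i
        p[L.P_NA_P_SHIFT] = it.na_p_shift
        p[L.P_PUMP_SCALE_E] = pu.scale_e
        return p

    # -- flat key/value serialization ----------------------------------------
    def to_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for section in (self.pyramidal, self.interneuron, self.pump, self.bath):
            for f in fields(section):
                out[f.name] = getattr(section, f.name)
        out["beta1"] = self.geometry.beta1
        out["beta2"] = self.geometry.beta2
        out["Vol_e"] = self.geometry.Vol_e
        out["T"] = self.constants.T
        out["C"] = self.constants.C_m
        return out

    def with_overrides(self, overrides: dict[str, float]) -> "ModelParameters":
        """Apply flat key/value overrides; unknown keys raise ``KeyError``."""
        params = self
        sections = {"pyramidal": PyramidalParameters,
                    "interneuron": InterneuronParameters,
                    "pump": PumpParameters,
                    "bath": BathParameters}
        known = {f.name: sec for sec, cls in sections.items()
                 for f in fields(cls)}
        geo_keys = {"beta1", "beta2", "Vol_e"}
        for key, value in overrides.items():
            value = float(value)
            if key in known:
                sec_name = known[key]
                sec = replace(getattr(params, sec_name), **{key: value})
                params = replace(params, **{sec_name: sec})
            elif key in geo_keys:
                geo = replace(params.geometry, **{key: value})
                params = replace(params, geometry=geo)
            elif key == "T":
                params = replace(params,
                                 constants=replace(params.constants, T=value))
            elif key == "C":
                params = replace(params,
                                 constants=replace(params.constants, C_m=value))
            else:
                raise KeyError(f"unknown parameter key {key!r}")
        return params


def load_parameters(source: Union[str, IO[str]],
                    base: ModelParameters | None = None) -> ModelParameters:
    """Load parameter overrides from a flat ``key: value`` text file (YAML)."""
    import yaml

    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("parameter file must contain a flat key/value mapping")
    return (base or ModelParameters()).with_overrides(data)
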