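"""State representations: the full 18-variable state and its 14-variable
reduction through the four first integrals.

In the reduced representation the four concentrations [K+]_e, [K+]_i,
[Na+]_o and [Cl-]_o are not integrated but recovered algebraically:

    [K+]_e  = gamma_e (v_e - H1) - [Na+]_e + [Cl-]_e
    [K+]_i  = gamma_i (v_i - H2) - [Na+]_i
    [Na+]_o = Na_sum - (Vol_e/Vol_o) [Na+]_e - (Vol_i/Vol_o) [Na+]_i
    [Cl-]_o = Cl_sum - (Vol_e/Vol_o) [Cl-]_e
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _layout as L
from .parameters import ModelParameters


@dataclass(frozen=True)
class ReducedState:
    """The 14 integrated variables of the reduced system."""

    v_e: float
    m_e: float
    h_e: float
    n_e: float
    Na_e: float
    Cl_e: float
    Ca_e: float
    s_e: float
    v_i: float
    h_i: float
    n_i: float
    Na_i: float
    s_i: float
    K_o: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in L.REDUCED_NAMES],
                        dtype=np.float64)

    @staticmethod
    def from_array(y: np.ndarray) -> "ReducedState":
        return ReducedState(*(float(x) for x in np.asarray(y)))

    # -- derived accessors ---------------------------------------------------
    def K_e(self, params: ModelParameters) -> float:
        t, g = params.totals, params.geometry
        return g.gamma_e * (self.v_e * params.constants.C_m - t.H1) \
            - self.Na_e + self.Cl_e

    def K_i(self, params: ModelParameters) -> float:
        t, g = params.totals, params.geometry
        return g.gamma_i * (self.v_i * params.constants.C_m - t.H2) - self.Na_i

    def Na_o(self, params: ModelParameters) -> float:
        t, g = params.totals, params.geometry
        return t.Na_sum - g.vol_frac_e * self.Na_e - g.vol_frac_i * self.Na_i

    def Cl_o(self, params: ModelParameters) -> float:
        t, g = params.totals, params.geometry
        return t.Cl_sum - g.vol_frac_e * self.Cl_e

    def lift(self, params: ModelParameters) -> "FullState":
        """Embed into the full 18-variable representation."""
        return FullState(*(getattr(self, n) for n in L.REDUCED_NAMES),
                         K_e=self.K_e(params), K_i=self.K_i(params),
                         Na_o=self.Na_o(params), Cl_o=self.Cl_o(params))


@dataclass(frozen=True)
class FullState:
    """All 18 state variables, with the extracellular/intracellular
    potassium, sodium and chloride carried explicitly."""

    v_e: float
    m_e: float
    h_e: float
    n_e: float
    Na_e: float
    Cl_e: float
    Ca_e: float
    s_e: float
    v_i: float
    h_i: float
    n_i: float
    Na_i: float
    s_i: float
    K_o: float
    K_e: float
    K_i: float
    Na_o: float
    Cl_o: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in L.FULL_NAMES],
                        dtype=np.float64)

    @staticmethod
    def from_array(y: np.ndarray) -> "FullState":
        return FullState(*(float(x) for x in np.asarray(y)))

    def reduce(self) -> ReducedState:
        return ReducedState(*(getattr(self, n) for n in L.REDUCED_NAMES))

    def validate(self) -> None:
        for name in ("m_e", "h_e", "n_e", "h_i", "n_i", "s_e", "s_i"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating/synaptic variable {name}={x} not in [0,1]")
        for name in ("K_e", "Na_e", "Cl_e", "K_i", "Na_i", "K_o", "Na_o", "Cl_o"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"concentration {name} must be positive")
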