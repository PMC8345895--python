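"""Physical constants, cell geometry and conserved bookkeeping quantities.

The model couples two spherical neurons (a pyramidal cell and a fast-spiking
GABAergic interneuron) to a shared extracellular space.  Transmembrane
currents (in uA/cm^2) are converted to concentration changes (mM/ms) through
the factor gamma = S / (1e3 * Vol * F) of each cell, and intracellular
changes map onto the extracellular compartment through the volume fractions
Vol_e/Vol_o and Vol_i/Vol_o.

Because every ionic current appears both in a membrane-potential equation and
in the matching concentration equations, the system carries four first
integrals: total sodium, total chloride, and one voltage/concentration
relation per neuron (H1 for the pyramidal cell, H2 for the interneuron).
Fixing them at the standard reference point (v = -70 mV, [Na]_in = 10 mM,
[K]_in = 140 mM, [Cl]_e = 5 mM, [K]_o = 3.5 mM, [Na]_o = 145 mM,
[Cl]_o = 130 mM) lets the state be reduced from 18 to 14 variables.

Units throughout the package: mV, ms, mM, uA/cm^2, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants at the model temperature (37 C).

    ``R`` is expressed in mJ/(K*mol) so that R*T/F is directly in mV.
    ``NA`` and ``e_charge`` are the rounded values used to derive the
    conversion factors; ``F = NA * e_charge``.
    """

    R: float = 8314.0          # mJ / (K mol)
    T: float = 309.15          # K
    NA: float = 6.02e23        # 1 / mol
    e_charge: float = 1.6e-19  # C
    C_m: float = 1.0           # uF / cm^2

    @property
    def F(self) -> float:
        """Faraday constant (C/mol)."""
        return self.NA * self.e_charge

    @property
    def RTF(self) -> float:
        """Thermal voltage R*T/F in mV (~26.7 mV at 309.15 K)."""
        return self.R * self.T / self.F


def sphere_area(volume: float) -> float:
    """Surface area (cm^2) of a sphere of the given volume (cm^3)."""
    return 4.0 * math.pi * (3.0 * volume / (4.0 * math.pi)) ** (2.0 / 3.0)


@dataclass(frozen=True)
class Geometry:
    """Compartment volumes, areas and current-to-concentration factors.

    ``beta1`` is the ratio of total intracellular volume to extracellular
    volume; ``beta2`` the interneuron/pyramidal volume ratio.  ``gamma_e``
    and ``gamma_i`` convert a membrane current density (uA/cm^2) into an
    intracellular concentration rate (mM/ms) for each cell.
    """

    Vol_e: float = 1.4368e-9   # cm^3, pyramidal volume
    beta1: float = 4.0
    beta2: float = 2.0 / 3.0
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    @property
    def Vol_i(self) -> float:
        return self.beta2 * self.Vol_e

    @property
    def S_e(self) -> float:
        return sphere_area(self.Vol_e)

    @property
    def S_i(self) -> float:
        return sphere_area(self.Vol_i)

    @property
    def gamma_e(self) -> float:
        """mol cm^2 / (uC L): ~4.45e-5 for the default pyramidal volume."""
        return self.S_e / (1e3 * self.Vol_e * self.constants.F)

    @property
    def gamma_i(self) -> float:
        """~5.09e-5 for the default interneuron volume."""
        return self.S_i / (1e3 * self.Vol_i * self.constants.F)

    @property
    def vol_frac_e(self) -> float:
        """Vol_e / Vol_o = beta1 / (1 + beta2)."""
        return self.beta1 / (1.0 + self.beta2)

    @property
    def vol_frac_i(self) -> float:
        """Vol_i / Vol_o = beta1 * beta2 / (1 + beta2)."""
        return self.beta1 * self.beta2 / (1.0 + self.beta2)


# Reference point at which the first integrals are pinned.
REF_V = -70.0        # mV
REF_NA_IN = 10.0     # mM (both neurons)
REF_K_IN = 140.0     # mM (both neurons)
REF_CL_IN = 5.0      # mM (pyramidal)
REF_K_OUT = 3.5      # mM
REF_NA_OUT = 145.0   # mM
REF_CL_OUT = 130.0   # mM


@dataclass(frozen=True)
class ConservedTotals:
    """First integrals of the full system, fixed at the reference point.

    ``Na_sum``/``Cl_sum`` are total-mass constants (mM, extracellular
    scale); ``H1``/``H2`` are the voltage/concentration integrals
    C*v - (1/gamma)*(sum of intracellular concentrations), kept in the
    units in which they arise (uA*ms/cm^2 scale, treated as bookkeeping
    constants).
    """

    geometry: Geometry = field(default_factory=Geometry)

    @property
    def Na_sum(self) -> float:
        return REF_NA_OUT + self.geometry.beta1 * REF_NA_IN

    @property
    def Cl_sum(self) -> float:
        return REF_CL_OUT + self.geometry.vol_frac_e * REF_CL_IN

    @property
    def H1(self) -> float:
        g = self.geometry
        return (g.constants.C_m * REF_V
                - (REF_NA_IN + REF_K_IN - REF_CL_IN) / g.gamma_e)

    @property
    def H2(self) -> float:
        g = self.geometry
        return (g.constants.C_m * REF_V
                - (REF_NA_IN + REF_K_IN) / g.gamma_i)
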