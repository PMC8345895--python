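"""Transmembrane currents: Nernst potentials, the pump, cotransporters,
per-mechanism currents and their net compositions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navmicro import (ConcentrationError, ModelParameters, pump_current,
                      pyramidal_currents, interneuron_currents,
                      reversal_potential)
from navmicro.parameters import PumpParameters

from conftest import random_reduced_states

RTF = ModelParameters().constants.RTF


class TestReversalPotential:
    def test_equal_concentrations_give_zero(self):
        assert reversal_potential(1, 12.0, 12.0, RTF) == 0.0

    def test_potassium_reversal_at_rest(self):
        # 3.5 mM out / 140 mM in at 309.15 K
        assert reversal_potential(1, 3.5, 140.0, RTF) == pytest.approx(
            -98.3, abs=0.3)

    def test_valence_scaling(self):
        e1 = reversal_potential(1, 20.0, 5.0, RTF)
        e2 = reversal_potential(2, 20.0, 5.0, RTF)
        assert e2 == pytest.approx(e1 / 2.0)

    def test_sign_flips_with_gradient(self):
        assert reversal_potential(1, 10.0, 100.0, RTF) < 0
        assert reversal_potential(1, 100.0, 10.0, RTF) > 0
        assert reversal_potential(-1, 10.0, 100.0, RTF) > 0

    def test_nonpositive_concentration_raises(self):
        with pytest.raises(ConcentrationError):
            reversal_potential(1, -1.0, 10.0, RTF)
        with pytest.raises(ConcentrationError):
            reversal_potential(1, 10.0, 0.0, RTF)
        with pytest.raises(ValueError):
            reversal_potential(0, 10.0, 10.0, RTF)


class TestPump:
    pump = PumpParameters()

    def test_half_activation_point(self):
        # both Hill factors at one half, v at the normalisation point
        value = pump_current(-70.0, 7.7, 2.0, self.pump, RTF)
        assert value == pytest.approx(30.0 / 8.0 / 4.0)

    def test_saturation(self):
        assert pump_current(-70.0, 1e9, 1e9, self.pump, RTF) == \
            pytest.approx(30.0, rel=1e-6)

    def test_against_term_by_term_oracle(self):
        v, na, ko = 0.0, 10.0, 3.5
        f = 0.5 * (1.0 + math.tanh(0.39 * v / RTF + 1.28))
        f70 = 0.5 * (1.0 + math.tanh(0.39 * (-70.0) / RTF + 1.28))
        expected = (30.0 * f / f70 * (na / (na + 7.7)) ** 3
                    * (ko / (ko + 2.0)) ** 2)
        assert pump_current(v, na, ko, self.pump, RTF) == \
            pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(v=st.floats(-90, 30), na=st.floats(1.0, 40.0),
           ko=st.floats(1.0, 40.0))
    def test_positive_and_monotone(self, v, na, ko):
        base = pump_current(v, na, ko, self.pump, RTF)
        assert base > 0
        assert pump_current(v + 5.0, na, ko, self.pump, RTF) > base
        assert pump_current(v, na + 1.0, ko, self.pump, RTF) > base
        assert pump_current(v, na, ko + 1.0, self.pump, RTF) > base


def _pyr(params, s):
    return pyramidal_currents(
        params, v_e=s.v_e, m_e=s.m_e, h_e=s.h_e, n_e=s.n_e,
        K_e=s.K_e(params), Na_e=s.Na_e, Cl_e=s.Cl_e, Ca_e=s.Ca_e,
        s_e=s.s_e, s_i=s.s_i, K_o=s.K_o, Na_o=s.Na_o(params),
        Cl_o=s.Cl_o(params))


def _int(params, s):
    return interneuron_currents(
        params, v_i=s.v_i, h_i=s.h_i, n_i=s.n_i, K_i=s.K_i(params),
        Na_i=s.Na_i, s_e=s.s_e, K_o=s.K_o, Na_o=s.Na_o(params))


class TestPyramidalCurrents:
    def test_kcc_vanishes_at_balanced_product(self, params):
        pc = pyramidal_currents(
            params, v_e=-70.0, m_e=0.01, h_e=0.9, n_e=0.1, K_e=140.0,
            Na_e=10.0, Cl_e=5.0, Ca_e=0.0, s_e=0.0, s_i=0.0,
            K_o=14.0, Na_o=145.0, Cl_o=50.0)
        # [K]_e[Cl]_e = 700 = [K]_o[Cl]_o
        assert pc.I_KCC == pytest.approx(0.0, abs=1e-12)

    def test_cotransporters_carry_no_net_charge(self, params):
        # at 1e4 random states, zeroing both cotransporters leaves the
        # total membrane current of the voltage equation unchanged
        from dataclasses import replace
        p0 = replace(params, pyramidal=replace(params.pyramidal,
                                               rho_KCC=0.0, rho_NKCC=0.0))
        states = random_reduced_states(10_000, seed=3)
        cols = {name: np.array([getattr(s, name) for s in states])
                for name in ("v_e", "m_e", "h_e", "n_e", "Na_e", "Cl_e",
                             "Ca_e", "s_e", "s_i", "K_o")}
        derived = dict(
            K_e=np.array([s.K_e(params) for s in states]),
            Na_o=np.array([s.Na_o(params) for s in states]),
            Cl_o=np.array([s.Cl_o(params) for s in states]))
        a = pyramidal_currents(params, **cols, **derived)
        b = pyramidal_currents(p0, **cols, **derived)
        total_a = a.I_Na_e + a.I_K_e + a.I_Cl_e
        total_b = b.I_Na_e + b.I_K_e + b.I_Cl_e
        np.testing.assert_allclose(total_a, total_b, rtol=1e-9, atol=1e-9)

    def test_glutamatergic_split_is_half_conductance_each(self, params):
        s = random_reduced_states(1, seed=7)[0]
        pc = _pyr(params, s)
        g = params.pyramidal.g_GLU_e
        assert pc.I_Na_GLU_e == pytest.approx(
            0.5 * g * s.s_e * (s.v_e - pc.E_Na_e))
        assert pc.I_K_GLU_e == pytest.approx(
            0.5 * g * s.s_e * (s.v_e - pc.E_K_e))

    def test_net_current_composition(self, params):
        # the printed stoichiometry: pump 3/-2, NKCC +1/+1/-2, KCC +1/-1
        s = random_reduced_states(1, seed=11)[0]
        pc = _pyr(params, s)
        assert pc.I_Na_e == pytest.approx(
            pc.I_Na_FI_e + pc.I_Na_L_e + 3 * pc.I_pump_e + pc.I_NKCC
            + pc.I_Na_GLU_e + pc.I_Na_D_e)
        assert pc.I_K_e == pytest.approx(
            pc.I_K_DR_e + pc.I_K_AHP_e + pc.I_K_L_e + pc.I_KCC + pc.I_NKCC
            - 2 * pc.I_pump_e + pc.I_K_GLU_e + pc.I_K_D_e)
        assert pc.I_Cl_e == pytest.approx(
            pc.I_Cl_L_e - pc.I_KCC - 2 * pc.I_NKCC + pc.I_GABA_e)


class TestInterneuronCurrents:
    def test_persistent_current_zero_without_conductance(self, params):
        s = random_reduced_states(1, seed=13)[0]
        ic = _int(params, s)  # wild type: g_Na_P_i = 0
        assert ic.I_Na_P_i == 0.0

    def test_ohmic_sodium_terms_vanish_at_reversal(self, params):
        from navmicro import MutationSpec
        p = params.with_mutation(MutationSpec.fhm3(20.0))
        s = random_reduced_states(1, seed=17)[0]
        ic0 = _int(p, s)
        # evaluate at v_i = E_Na,i: all sodium ohmic terms must vanish
        from dataclasses import replace as dreplace
        s2 = dreplace(s, v_i=float(ic0.E_Na_i))
        # E_Na depends only on concentrations, unchanged by v_i
        ic = _int(p, s2)
        assert ic.I_Na_FI_i == pytest.approx(0.0, abs=1e-9)
        assert ic.I_Na_P_i == pytest.approx(0.0, abs=1e-9)
        assert ic.I_Na_L_i == pytest.approx(0.0, abs=1e-9)

    def test_persistent_current_uses_shifted_activation(self, params):
        from navmicro import MutationSpec, interneuron_gating
        p = params.with_mutation(MutationSpec.fhm3(20.0))
        ic = interneuron_currents(p, v_i=-32.0, h_i=0.0, n_i=0.0,
                                  K_i=140.0, Na_i=10.0, s_e=0.0,
                                  K_o=3.5, Na_o=145.0)
        # activation evaluated at -32 + 8 = -24 mV, the sigmoid midpoint
        g_p = p.interneuron.g_Na_P_i
        expected = g_p * 0.5 ** 3 * (-32.0 - ic.E_Na_i)
        assert ic.I_Na_P_i == pytest.approx(expected, rel=1e-12)
        assert ic.I_Na_P_i < 0  # inward below the sodium reversal

    def test_interneuron_has_no_chloride_pathway(self, params):
        s = random_reduced_states(1, seed=19)[0]
        ic = _int(params, s)
        names = {f for f in ic.__dataclass_fields__}
        assert not any("Cl" in n for n in names)
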