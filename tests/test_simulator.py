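"""Integration machinery: events, rest states, state-mode equivalence,
step-size convergence and conservation along trajectories."""

import numpy as np
import pytest

from navmicro import (ModelParameters, MutationSpec, SimulationConfig,
                      find_isolated_rest_state, find_rest_state, integrate,
                      rhs_reduced, standard_state)


def test_zero_duration_returns_single_sample(params):
    cfg = SimulationConfig(mode="coupled", duration=0.0)
    trace, events = integrate(cfg)
    assert len(trace) == 1
    assert len(events.pyramidal) == 0 and len(events.gabaergic) == 0


def test_sample_count_contract(params):
    cfg = SimulationConfig(mode="coupled", duration=100.0, dt=0.02,
                           record_stride=7)
    trace, _ = integrate(cfg)
    assert len(trace) == int(100.0 / 0.02) // 7 + 1
    assert np.all(np.diff(trace.time) > 0)


def test_rest_state_is_equilibrium_and_stationary(params):
    rest = find_rest_state(params)
    residual = rhs_reduced(rest, params.with_drives(0.0, 0.0))
    assert np.max(np.abs(residual)) < 1e-9
    # extracellular potassium equilibrates to the bath value
    assert rest.K_o == pytest.approx(3.5, abs=0.2)
    # 10 s of drift-free integration from the equilibrium
    cfg = SimulationConfig(mode="coupled", duration=10_000.0)
    trace, events = integrate(cfg, init=rest)
    assert len(events.pyramidal) == 0 and len(events.gabaergic) == 0
    drift = np.abs(trace.data.iloc[-1][list(rest.__dict__)]
                   - np.array(list(rest.__dict__.values())))
    assert float(drift.max()) < 1e-6


def test_isolated_rest_state_is_stationary(params):
    rest = find_isolated_rest_state(params)
    cfg = SimulationConfig(mode="isolated_interneuron", duration=5_000.0)
    trace, events = integrate(cfg, init=rest)
    assert len(events.gabaergic) == 0
    assert trace["v_i"][-1] == pytest.approx(rest.v_i, abs=1e-6)
    assert trace["Na_i"][-1] == pytest.approx(rest.Na_i, abs=1e-6)
    assert trace["K_o"][-1] == pytest.approx(rest.K_o, abs=1e-6)


def test_rest_state_depends_on_mutation(params):
    rest_wt = find_isolated_rest_state(params)
    rest_mut = find_isolated_rest_state(
        params.with_mutation(MutationSpec.fhm3(20.0)))
    # the persistent current depolarizes the interneuron's rest potential
    assert rest_mut.v_i > rest_wt.v_i


def test_synaptic_reset_coincides_with_threshold_crossing():
    cfg = SimulationConfig(mode="isolated_interneuron", g_D_i=0.1,
                           duration=200.0, record_stride=1)
    trace, events = integrate(cfg)
    assert len(events.gabaergic) >= 3
    assert np.all(np.diff(events.gabaergic) > 0)  # strictly increasing
    s_i = trace["s_i"]
    v_i = trace["v_i"]
    t = trace.time
    dt = t[1] - t[0]
    for spike in events.gabaergic:
        k = int(np.searchsorted(t, spike))
        # the synaptic variable is set to 1 at the end of the crossing
        # step (at most one decay step separates it from the sample)
        window = s_i[max(k - 1, 0): k + 2]
        assert window.max() >= np.exp(-dt / 9.0) - 1e-12
        # and the voltage crosses 0 mV upward there
        assert v_i[k - 1] < 0.0 <= v_i[min(k + 1, len(v_i) - 1)] + 1e-12


def test_reduced_and_full_modes_agree():
    kw = dict(mode="coupled", mutation=MutationSpec.fhm3(15.0), g_D_e=0.3,
              g_D_i=0.3, duration=1000.0, record_stride=10)
    tr_red, ev_red = integrate(SimulationConfig(state_mode="reduced", **kw))
    tr_full, ev_full = integrate(SimulationConfig(state_mode="full", **kw))
    assert len(ev_red.pyramidal) == len(ev_full.pyramidal)
    assert len(ev_red.gabaergic) == len(ev_full.gabaergic)
    np.testing.assert_allclose(ev_red.gabaergic, ev_full.gabaergic,
                               atol=1e-6)
    for col in ("v_e", "v_i"):
        np.testing.assert_allclose(tr_red[col], tr_full[col], atol=1e-6)
    for col in ("Na_e", "Na_i", "K_o", "K_e", "K_i", "Na_o", "Cl_o"):
        np.testing.assert_allclose(tr_red[col], tr_full[col], atol=1e-6)


def test_first_integrals_conserved_along_trajectory(params):
    """Na/Cl totals and both H integrals drift < 1e-6 relative per
    simulated second in a vigorously spiking full-state run."""
    cfg = SimulationConfig(mode="coupled", mutation=MutationSpec.fhm3(15.0),
                           g_D_e=0.3, g_D_i=0.3, duration=2000.0,
                           state_mode="full")
    trace, _ = integrate(cfg)
    g, t = params.geometry, params.totals
    na_tot = (g.vol_frac_e * trace["Na_e"] + g.vol_frac_i * trace["Na_i"]
              + trace["Na_o"])
    cl_tot = g.vol_frac_e * trace["Cl_e"] + trace["Cl_o"]
    h1 = trace["v_e"] - (trace["Na_e"] + trace["K_e"]
                         - trace["Cl_e"]) / g.gamma_e
    h2 = trace["v_i"] - (trace["Na_i"] + trace["K_i"]) / g.gamma_i
    seconds = 2.0
    for series, ref in ((na_tot, t.Na_sum), (cl_tot, t.Cl_sum),
                        (h1, t.H1), (h2, t.H2)):
        rel_drift = np.max(np.abs(series - ref)) / abs(ref) / seconds
        assert rel_drift < 1e-6


def test_spike_times_converge_under_dt_halving():
    kw = dict(mode="isolated_interneuron", g_D_i=0.3, duration=1000.0)
    _, ev1 = integrate(SimulationConfig(dt=0.01, record_stride=10, **kw))
    _, ev2 = integrate(SimulationConfig(dt=0.005, record_stride=20, **kw))
    n = min(len(ev1.gabaergic), len(ev2.gabaergic))
    assert n >= 50
    assert np.max(np.abs(ev1.gabaergic[:n] - ev2.gabaergic[:n])) < 0.1


def test_strong_na_buffering_holds_extracellular_sodium():
    cfg = SimulationConfig(mode="isolated_interneuron", g_D_i=0.3,
                           duration=200.0)
    tr_plain, _ = integrate(cfg)
    cfg_b = SimulationConfig(mode="coupled", mutation=MutationSpec.fhm3(15.0),
                             g_D_e=0.3, g_D_i=0.3, duration=500.0,
                             buffering="strong_Na")
    tr_buf, _ = integrate(cfg_b)
    na = tr_buf["Na_o"]
    assert abs(na[-1] - na[0]) < 1.0  # clamped near its bath value
    # without buffering the same scenario moves sodium appreciably
    cfg_n = SimulationConfig(mode="coupled", mutation=MutationSpec.fhm3(15.0),
                             g_D_e=0.3, g_D_i=0.3, duration=500.0)
    tr_n, _ = integrate(cfg_n)
    assert abs(tr_n["Na_o"][-1] - tr_n["Na_o"][0]) > \
        abs(na[-1] - na[0])


def test_buffering_none_leaves_dynamics_unchanged():
    kw = dict(mode="isolated_interneuron", g_D_i=0.2, duration=300.0)
    tr1, _ = integrate(SimulationConfig(buffering="none", **kw))
    tr2, _ = integrate(SimulationConfig(**kw))
    np.testing.assert_array_equal(tr1["v_i"], tr2["v_i"])


def test_invalid_configurations_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(dt=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(duration=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(mode="network")
    with pytest.raises(ValueError):
        SimulationConfig(buffering="strong_Ca")


def test_standard_state_matches_reference_concentrations(params):
    s = standard_state(params)
    assert (s.Na_e, s.Cl_e, s.K_o, s.Na_i) == (10.0, 5.0, 3.5, 10.0)
    assert s.K_e(params) == pytest.approx(140.0)
    assert s.K_i(params) == pytest.approx(140.0)
    assert s.Na_o(params) == pytest.approx(145.0)
    assert s.Cl_o(params) == pytest.approx(130.0)
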