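"""Protocol analyses on synthetic waveforms and short simulations."""

import numpy as np
import pandas as pd
import pytest

from navmicro import EventLog, ModelParameters, MutationSpec
from navmicro.protocols import (ap_features, count_overshooting_spikes,
                                detect_depolarization_block,
                                gaba_current_running_average,
                                instantaneous_frequency, io_curve, rheobase,
                                sustained_firing_onset)
from navmicro.simulator import Trace


def synthetic_trace(v: np.ndarray, dt: float = 0.1,
                    neuron_col: str = "v_i") -> Trace:
    """Wrap a bare voltage series in an isolated-interneuron-like trace."""
    n = len(v)
    params = ModelParameters()
    data = pd.DataFrame({
        neuron_col: v,
        "h_i": np.full(n, 0.5), "n_i": np.full(n, 0.2),
        "Na_i": np.full(n, 10.0), "s_i": np.zeros(n),
        "K_o": np.full(n, 3.5), "K_i": np.full(n, 140.0),
        "Na_o": np.full(n, 145.0)})
    return Trace(time=np.arange(n) * dt, data=data, params=params,
                 mode="isolated_interneuron")


class TestSpikeCounting:
    def test_flat_trace_has_no_spikes(self):
        tr = synthetic_trace(np.full(1000, -70.0))
        assert count_overshooting_spikes(tr, "gabaergic") == 0

    def test_only_overshooting_peaks_count(self):
        # three bumps peaking at +20, -5 and +10 mV
        t = np.linspace(0, 3, 3000)
        v = np.full_like(t, -70.0)
        for center, peak in ((0.5, 20.0), (1.5, -5.0), (2.5, 10.0)):
            bump = (peak + 70.0) * np.exp(-((t - center) / 0.05) ** 2)
            v = np.maximum(v, -70.0 + bump)
        assert count_overshooting_spikes(synthetic_trace(v), "gabaergic") == 2

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            count_overshooting_spikes(synthetic_trace(np.empty(0)),
                                      "gabaergic")


class TestAPFeatures:
    def test_triangular_spike_half_width_is_half_base(self):
        # symmetric triangular spike of base width w: time above the
        # midpoint between baseline and peak is exactly w/2
        dt = 0.01
        w = 2.0  # ms
        t = np.arange(0, 10, dt)
        v = np.full_like(t, -70.0)
        apex = 5.0
        rise = np.abs(t - apex) <= w / 2
        v[rise] = -70.0 + 90.0 * (1 - np.abs(t[rise] - apex) / (w / 2))
        feats = ap_features(synthetic_trace(v, dt=dt), "gabaergic")
        assert len(feats) == 1
        assert feats[0].half_width_ms == pytest.approx(w / 2, rel=0.02)
        assert feats[0].peak_mV == pytest.approx(20.0, abs=1.0)

    def test_no_spike_raises(self):
        with pytest.raises(ValueError):
            ap_features(synthetic_trace(np.full(100, -70.0)), "gabaergic")

    def test_half_widths_increase_with_persistent_current(self, iso_run_p0,
                                                          iso_run_p20):
        f0 = ap_features(iso_run_p0[0], "gabaergic")
        f20 = ap_features(iso_run_p20[0], "gabaergic")
        assert f20[24].half_width_ms > f0[24].half_width_ms
        # larger per-spike extracellular potassium accumulation as well
        assert f20[24].dK_o > f0[24].dK_o
        assert f20[24].dNa_o < f0[24].dNa_o  # stronger Na uptake


class TestInstantaneousFrequency:
    def test_regular_train(self):
        ev = EventLog(pyramidal=np.empty(0),
                      gabaergic=np.array([0.0, 10.0, 20.0]))
        f = instantaneous_frequency(ev, "gabaergic")
        assert list(f["frequency_Hz"]) == [100.0, 100.0]
        assert list(f["time_ms"]) == [10.0, 20.0]

    def test_fewer_than_two_spikes_gives_empty_series(self):
        ev = EventLog(pyramidal=np.array([5.0]), gabaergic=np.empty(0))
        assert instantaneous_frequency(ev, "pyramidal").empty
        assert instantaneous_frequency(ev, "gabaergic").empty


class TestBlockDetection:
    def test_constant_depolarized_trace_blocks_at_zero(self):
        tr = synthetic_trace(np.full(20_000, -40.0))
        ev = detect_depolarization_block(tr, "gabaergic")
        assert ev is not None and ev.onset_ms == 0.0
        assert ev.terminal_voltage_mV == -40.0

    def test_resting_trace_is_not_block(self):
        # -70 mV fails the terminal-voltage range condition
        tr = synthetic_trace(np.full(20_000, -70.0))
        assert detect_depolarization_block(tr, "gabaergic") is None

    def test_tonic_spiking_is_not_block(self):
        t = np.arange(20_000) * 0.1
        v = -40.0 + 40.0 * np.sin(2 * np.pi * t / 20.0)
        assert detect_depolarization_block(synthetic_trace(v),
                                           "gabaergic") is None

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            detect_depolarization_block(synthetic_trace(np.full(100, -40.0)),
                                        "gabaergic")

    def test_onset_is_start_of_first_qualifying_window(self):
        v = np.concatenate([np.full(5000, -70.0), np.full(10_000, -40.0)])
        ev = detect_depolarization_block(synthetic_trace(v), "gabaergic")
        assert ev is not None
        assert ev.onset_ms == pytest.approx(500.0, abs=0.2)


class TestRunningAverage:
    def test_constant_series_is_unchanged(self):
        tr = synthetic_trace(np.full(5000, -60.0), neuron_col="v_e")
        tr.data["Cl_e"] = 5.0
        tr.data["Cl_o"] = 130.0
        tr.data["s_i"] = 0.3
        avg = gaba_current_running_average(tr)["I_GABA_e"].to_numpy()
        assert np.allclose(avg, avg[0])

    def test_zero_synaptic_variable_gives_zero_current(self):
        tr = synthetic_trace(np.full(5000, -60.0), neuron_col="v_e")
        tr.data["Cl_e"] = 5.0
        tr.data["Cl_o"] = 130.0
        avg = gaba_current_running_average(tr)["I_GABA_e"].to_numpy()
        assert np.allclose(avg, 0.0)


class TestSustainedOnset:
    def test_isolated_transient_is_ignored(self):
        ev = EventLog(pyramidal=np.array([1.0] + list(
            np.arange(3000.0, 3500.0, 100.0))), gabaergic=np.empty(0))
        assert sustained_firing_onset(ev, "pyramidal") == 3000.0

    def test_no_sustained_firing(self):
        ev = EventLog(pyramidal=np.array([1.0, 5000.0]),
                      gabaergic=np.empty(0))
        assert sustained_firing_onset(ev, "pyramidal") is None


class TestIOProtocols:
    def test_zero_drive_point_stays_at_rest(self):
        curve = io_curve(MutationSpec.wild_type(), [0.0], duration_ms=100.0)
        assert curve.spike_count[0] == 0
        assert curve.K_o_end[0] == pytest.approx(3.5, abs=0.05)

    def test_persistent_current_boosts_weak_input_response(self):
        g = [0.02, 0.05]
        c0 = io_curve(MutationSpec.wild_type(), g, duration_ms=200.0)
        c20 = io_curve(MutationSpec.fhm3(20.0), g, duration_ms=200.0)
        assert np.all(c20.spike_count >= c0.spike_count)

    def test_rheobase_monotone_in_persistent_fraction(self):
        values = [rheobase(MutationSpec.fhm3(p) if p else
                           MutationSpec.wild_type())
                  for p in (0.0, 10.0, 20.0)]
        assert all(v is not None for v in values)
        assert values[0] >= values[1] >= values[2]
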