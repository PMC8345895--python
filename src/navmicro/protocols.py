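"""Quantitative stimulation protocols and trace analyses.

Implements the experiments used to characterize the model: input-output
curves and rheobase of the isolated interneuron, per-action-potential
features (half-width, action currents, per-spike ion displacements),
instantaneous firing frequency, depolarization-block detection, the
threshold and latency of cortical-spreading-depolarization (CSD)
initiation in the coupled circuit, and the epilepsy-scenario analyses.

Definitions
-----------
* An *overshooting spike* is a local voltage maximum exceeding 0 mV, with
  successive maxima separated by a downward crossing of 0 mV.
* *Depolarization block*: a 500 ms window in which the voltage oscillates
  by less than 5 mV and ends between -55 and -20 mV.  The onset reported
  is the start time of the first qualifying window.
* *CSD initiation* = the pyramidal neuron meeting the depolarization-block
  criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .currents import interneuron_currents
from .parameters import ModelParameters, MutationSpec
from .simulator import EventLog, SimulationConfig, Trace, integrate

BLOCK_WINDOW_MS = 500.0
BLOCK_AMPLITUDE_MV = 5.0
BLOCK_V_RANGE = (-55.0, -20.0)
MAX_DRIVE = 0.3  # mS/cm^2; stronger inputs are considered unphysiological


_VOLTAGE_COLUMN = {"pyramidal": "v_e", "gabaergic": "v_i"}


def _voltage(trace: Trace, neuron: str) -> np.ndarray:
    col = _VOLTAGE_COLUMN[neuron]
    if col not in trace.data.columns:
        raise KeyError(f"trace has no voltage for neuron {neuron!r}")
    return trace[col]


# ---------------------------------------------------------------------------
# Spike counting and AP features
# ---------------------------------------------------------------------------

def _overshoot_segments(v: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous index ranges where v > 0, i.e. one per overshooting AP."""
    above = v > 0.0
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    return list(zip(starts, ends))


def count_overshooting_spikes(trace: Trace, neuron: str) -> int:
    """Number of voltage maxima above 0 mV separated by 0 mV down-crossings."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    return len(_overshoot_segments(_voltage(trace, neuron)))


@dataclass(frozen=True)
class APFeatures:
    """Shape and flux summary of one action potential.

    ``half_width`` is the time spent above the midpoint between the
    preceding inter-spike minimum and the peak.  The current extrema and
    the per-AP extracellular increments are evaluated on the window from
    the preceding inter-spike minimum to the next one.
    """

    index: int
    peak_mV: float
    peak_time_ms: float
    half_width_ms: float
    I_K_extremum: float
    I_Na_extremum: float
    dK_o: float
    dNa_o: float


def _interp_crossing(t: np.ndarray, v: np.ndarray, i0: int, i1: int,
                     level: float) -> float:
    return t[i0] + (t[i1] - t[i0]) * (level - v[i0]) / (v[i1] - v[i0])


def ap_features(trace: Trace, neuron: str = "gabaergic") -> list[APFeatures]:
    """Per-action-potential features of an interneuron (or pyramidal) trace.

    Requires at least one overshooting spike and benefits from fine
    sampling (record_stride=1 at dt = 0.01 ms for half-width accuracy).
    """
    t = trace.time
    v = _voltage(trace, neuron)
    segs = _overshoot_segments(v)
    if not segs:
        raise ValueError("trace contains no overshooting spike")
    peaks = [s + int(np.argmax(v[s:e])) for s, e in segs]

    if neuron == "gabaergic":
        cur = interneuron_currents(
            trace.params, v_i=v, h_i=trace["h_i"], n_i=trace["n_i"],
            K_i=trace["K_i"], Na_i=trace["Na_i"],
            s_e=(trace["s_e"] if "s_e" in trace.data.columns
                 else np.zeros_like(v)),
            K_o=trace["K_o"], Na_o=trace["Na_o"])
        I_K, I_Na = cur.I_K_i, cur.I_Na_i
    else:
        from .currents import pyramidal_currents
        cur = pyramidal_currents(
            trace.params, v_e=v, m_e=trace["m_e"], h_e=trace["h_e"],
            n_e=trace["n_e"], K_e=trace["K_e"], Na_e=trace["Na_e"],
            Cl_e=trace["Cl_e"], Ca_e=trace["Ca_e"], s_e=trace["s_e"],
            s_i=trace["s_i"], K_o=trace["K_o"], Na_o=trace["Na_o"],
            Cl_o=trace["Cl_o"])
        I_K, I_Na = cur.I_K_e, cur.I_Na_e

    K_o, Na_o = trace["K_o"], trace["Na_o"]
    out: list[APFeatures] = []
    for k, pk in enumerate(peaks):
        # window: preceding inter-spike minimum to the following one
        lo_from = peaks[k - 1] if k > 0 else 0
        base_i = lo_from + int(np.argmin(v[lo_from:pk]))
        hi_to = peaks[k + 1] if k + 1 < len(peaks) else len(v)
        next_i = pk + int(np.argmin(v[pk:hi_to]))
        half = 0.5 * (v[base_i] + v[pk])
        i = pk
        while i > 0 and v[i] > half:
            i -= 1
        t_up = _interp_crossing(t, v, i, i + 1, half)
        j = pk
        while j < len(v) - 1 and v[j] > half:
            j += 1
        t_dn = _interp_crossing(t, v, j - 1, j, half)
        i_k_win = I_K[base_i:next_i + 1]
        i_na_win = I_Na[base_i:next_i + 1]
        out.append(APFeatures(
            index=k, peak_mV=float(v[pk]), peak_time_ms=float(t[pk]),
            half_width_ms=float(t_dn - t_up),
            I_K_extremum=float(i_k_win[np.argmax(np.abs(i_k_win))]),
            I_Na_extremum=float(i_na_win[np.argmax(np.abs(i_na_win))]),
            dK_o=float(K_o[next_i] - K_o[base_i]),
            dNa_o=float(Na_o[next_i] - Na_o[base_i])))
    return out


def instantaneous_frequency(events: EventLog, neuron: str) -> pd.DataFrame:
    """Inverse interspike interval (Hz), reported at the later spike time."""
    spikes = events.pyramidal if neuron == "pyramidal" else events.gabaergic
    if len(spikes) < 2:
        return pd.DataFrame(columns=["time_ms", "frequency_Hz"])
    isi = np.diff(spikes)
    return pd.DataFrame({"time_ms": spikes[1:], "frequency_Hz": 1000.0 / isi})


def sustained_firing_onset(events: EventLog, neuron: str,
                           min_spikes: int = 5,
                           within_ms: float = 1000.0) -> float | None:
    """First spike that is followed by at least ``min_spikes - 1`` further
    spikes within ``within_ms`` (filters out isolated stimulus-onset
    transients)."""
    spikes = events.pyramidal if neuron == "pyramidal" else events.gabaergic
    for k in range(len(spikes) - min_spikes + 1):
        if spikes[k + min_spikes - 1] - spikes[k] <= within_ms:
            return float(spikes[k])
    return None


# ---------------------------------------------------------------------------
# Depolarization block
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockEvent:
    onset_ms: float
    terminal_voltage_mV: float


def detect_depolarization_block(trace: Trace, neuron: str,
                                window_ms: float = BLOCK_WINDOW_MS
                                ) -> BlockEvent | None:
    """First window of low-amplitude depolarized voltage, or ``None``.

    A window of length ``window_ms`` qualifies iff max(v) - min(v) < 5 mV
    and the voltage at the window end lies in [-55, -20] mV.
    """
    t = trace.time
    v = _voltage(trace, neuron)
    if len(t) < 2 or t[-1] - t[0] < window_ms:
        raise ValueError("trace shorter than the block-detection window")
    dt = t[1] - t[0]
    w = int(round(window_ms / dt))
    # forward-looking extrema over [i, i + w)
    mx = ndimage.maximum_filter1d(v, w, origin=-(w // 2))[: len(v) - w + 1]
    mn = ndimage.minimum_filter1d(v, w, origin=-(w // 2))[: len(v) - w + 1]
    v_end = v[w - 1:]
    ok = ((mx - mn < BLOCK_AMPLITUDE_MV)
          & (v_end >= BLOCK_V_RANGE[0]) & (v_end <= BLOCK_V_RANGE[1]))
    if not ok.any():
        return None
    i = int(np.argmax(ok))
    return BlockEvent(onset_ms=float(t[i]),
                      terminal_voltage_mV=float(v_end[i]))


# ---------------------------------------------------------------------------
# Input-output protocols (isolated interneuron)
# ---------------------------------------------------------------------------

@dataclass
class IOCurve:
    """Spike counts and terminal extracellular concentrations vs drive."""

    g_D_i: np.ndarray
    spike_count: np.ndarray
    K_o_end: np.ndarray
    Na_o_end: np.ndarray
    blocked: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "g_D_i": self.g_D_i, "spike_count": self.spike_count,
            "K_o_end_mM": self.K_o_end, "Na_o_end_mM": self.Na_o_end,
            "depolarization_block": self.blocked})


def io_curve(mutation: MutationSpec, grid, duration_ms: float = 400.0,
             dt: float = 0.01,
             base_params: ModelParameters | None = None) -> IOCurve:
    """Isolated-interneuron input-output relationship.

    One simulation from the isolated rest state per drive value; records
    the overshooting-spike count and the terminal [K+]_o / [Na+]_o.
    Points that end in depolarization block are flagged so that firing
    comparisons can exclude them.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    counts, k_end, na_end, blocked = [], [], [], []
    for g in grid:
        cfg = SimulationConfig(mode="isolated_interneuron", mutation=mutation,
                               g_D_i=float(g), duration=duration_ms, dt=dt,
                               record_stride=5)
        trace, _ = integrate(cfg, base_params=base_params)
        counts.append(count_overshooting_spikes(trace, "gabaergic"))
        k_end.append(trace["K_o"][-1])
        na_end.append(trace["Na_o"][-1])
        if duration_ms >= BLOCK_WINDOW_MS:
            blocked.append(
                detect_depolarization_block(trace, "gabaergic") is not None)
        else:
            blocked.append(False)
    return IOCurve(g_D_i=grid, spike_count=np.array(counts, dtype=int),
                   K_o_end=np.array(k_end), Na_o_end=np.array(na_end),
                   blocked=np.array(blocked, dtype=bool))


def rheobase(mutation: MutationSpec, duration_ms: float = 400.0,
             dt: float = 0.01,
             base_params: ModelParameters | None = None) -> float | None:
    """Minimal drive eliciting at least one overshooting spike.

    Bisection on g_D_i over [0, 0.3] until the bracket is narrower than
    5e-5 mS/cm^2; returns the bracket midpoint rounded to 1e-4, or
    ``None`` if even the maximal drive elicits no spike.
    """
    def fires(g: float) -> bool:
        cfg = SimulationConfig(mode="isolated_interneuron", mutation=mutation,
                               g_D_i=g, duration=duration_ms, dt=dt,
                               record_stride=5)
        trace, _ = integrate(cfg, base_params=base_params)
        return count_overshooting_spikes(trace, "gabaergic") >= 1

    lo, hi = 0.0, MAX_DRIVE
    if not fires(hi):
        return None
    while hi - lo > 5e-5:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return round(0.5 * (lo + hi), 4)


# ---------------------------------------------------------------------------
# CSD threshold / latency (coupled circuit)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the drive bisection for pyramidal depolarization block.

    ``value`` is the smallest bracket endpoint whose predicate is true
    (``None`` when block is not reached at the maximal drive); the final
    bracket and its predicate values are reported because the response can
    alternate between block and no-block very close to the threshold.
    """

    mutation: MutationSpec
    value: float | None
    bracket: tuple[float, float]
    bracket_predicates: tuple[bool, bool]


def _coupled_block(mutation: MutationSpec, g: float, duration_ms: float,
                   neuron: str, dt: float,
                   base_params: ModelParameters | None = None,
                   buffering: str = "none",
                   eps_override: float | None = None) -> BlockEvent | None:
    cfg = SimulationConfig(mode="coupled", mutation=mutation, g_D_e=g,
                           g_D_i=g, duration=duration_ms, dt=dt,
                           buffering=buffering, eps_override=eps_override)
    trace, _ = integrate(cfg, base_params=base_params)
    return detect_depolarization_block(trace, neuron)


def csd_threshold(mutation: MutationSpec, duration_ms: float = 30_000.0,
                  n_iter: int = 13, dt: float = 0.01,
                  base_params: ModelParameters | None = None,
                  buffering: str = "none",
                  eps_override: float | None = None) -> ThresholdResult:
    """Minimal common drive g_D,e = g_D,i inducing pyramidal block.

    13 bisection iterations on [0, 0.3] (final bracket < 4e-5 mS/cm^2);
    the predicate is evaluated on both bracket endpoints in the returned
    result.
    """
    def blocked(g: float) -> bool:
        return _coupled_block(mutation, g, duration_ms, "pyramidal", dt,
                              base_params, buffering, eps_override) is not None

    lo, hi = 0.0, MAX_DRIVE
    if not blocked(hi):
        return ThresholdResult(mutation, None, (lo, hi), (False, False))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if blocked(mid):
            hi = mid
        else:
            lo = mid
    return ThresholdResult(mutation, hi, (lo, hi), (blocked(lo), True))


def csd_latency(mutation: MutationSpec, g: float = MAX_DRIVE,
                duration_ms: float = 30_000.0, dt: float = 0.01,
                base_params: ModelParameters | None = None,
                buffering: str = "none",
                eps_override: float | None = None) -> float | None:
    """Onset time (ms) of pyramidal depolarization block, or ``None``."""
    event = _coupled_block(mutation, g, duration_ms, "pyramidal", dt,
                           base_params, buffering, eps_override)
    return None if event is None else event.onset_ms


def gaba_block_onset(mutation: MutationSpec | None = None,
                     g: float = MAX_DRIVE, duration_ms: float = 30_000.0,
                     dt: float = 0.01,
                     base_params: ModelParameters | None = None
                     ) -> float | None:
    """Onset time (ms) of interneuron depolarization block in the coupled
    circuit (the epilepsy scenario when used with the loss-of-function
    variant)."""
    if mutation is None:
        mutation = MutationSpec.epileptogenic()
    event = _coupled_block(mutation, g, duration_ms, "gabaergic", dt,
                           base_params)
    return None if event is None else event.onset_ms


# ---------------------------------------------------------------------------
# Scenario comparison helpers
# ---------------------------------------------------------------------------

def gaba_current(trace: Trace) -> np.ndarray:
    """Inhibitory GABA-A chloride current onto the pyramidal cell
    (uA/cm^2, positive = outward = hyperpolarizing)."""
    params = trace.params
    RTF = params.constants.RTF
    E_Cl = -RTF * np.log(trace["Cl_o"] / trace["Cl_e"])
    return params.pyramidal.g_GABA_e * trace["s_i"] * (trace["v_e"] - E_Cl)


def gaba_current_running_average(trace: Trace,
                                 window_ms: float = 200.0) -> pd.DataFrame:
    """Centered running average of the GABAergic current, truncated at the
    trace edges."""
    i_gaba = gaba_current(trace)
    dt = trace.time[1] - trace.time[0] if len(trace) > 1 else 1.0
    w = max(int(round(window_ms / dt)), 1)
    avg = (pd.Series(i_gaba)
           .rolling(window=w, center=True, min_periods=1).mean().to_numpy())
    return pd.DataFrame({"time_ms": trace.time, "I_GABA_e": avg})


@dataclass(frozen=True)
class ScenarioSummary:
    """Headline quantities of one coupled 30 s scenario."""

    mutation: MutationSpec
    pyramidal_block_ms: float | None
    gabaergic_block_ms: float | None
    K_o_max: float
    pyramidal_spikes: int
    gabaergic_spikes: int
    min_gaba_running_avg: float = field(default=float("nan"))


def compare_scenarios(mutations: list[MutationSpec] | None = None,
                      g: float = MAX_DRIVE, duration_ms: float = 30_000.0,
                      dt: float = 0.01,
                      base_params: ModelParameters | None = None
                      ) -> list[ScenarioSummary]:
    """Run the control / migraine / epilepsy scenarios side by side."""
    if mutations is None:
        mutations = [MutationSpec.wild_type(), MutationSpec.fhm3(15.0),
                     MutationSpec.epileptogenic()]
    out = []
    for mut in mutations:
        cfg = SimulationConfig(mode="coupled", mutation=mut, g_D_e=g,
                               g_D_i=g, duration=duration_ms, dt=dt)
        trace, events = integrate(cfg, base_params=base_params)
        blk_e = detect_depolarization_block(trace, "pyramidal")
        blk_i = detect_depolarization_block(trace, "gabaergic")
        avg = gaba_current_running_average(trace)["I_GABA_e"].to_numpy()
        out.append(ScenarioSummary(
            mutation=mut,
            pyramidal_block_ms=None if blk_e is None else blk_e.onset_ms,
            gabaergic_block_ms=None if blk_i is None else blk_i.onset_ms,
            K_o_max=float(trace["K_o"].max()),
            pyramidal_spikes=len(events.pyramidal),
            gabaergic_spikes=len(events.gabaergic),
            min_gaba_running_avg=float(np.min(avg))))
    return out
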