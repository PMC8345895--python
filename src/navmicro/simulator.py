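"""Fixed-step simulation of the microcircuit with spike-event synaptic
resets, rest-state initialization and scenario configuration.

The reference integration scheme is classical 4th-order Runge-Kutta with a
fixed step (default 0.01 ms).  Spike events are detected between
consecutive steps: when a membrane potential crosses its spike threshold
upward, the corresponding synaptic variable is set to 1 at the end of the
crossing step and the crossing time is logged by linear interpolation.

Three scenario modes are supported:

* ``coupled`` -- the full two-neuron system (reduced 14-variable state by
  default; an 18-variable full-state mode is kept as a cross-validation
  path and is required when sodium bath exchange breaks conservation);
* ``isolated_interneuron`` -- the pyramidal cell frozen at its rest state
  and removed from the extracellular bookkeeping, so that only the
  interneuron's own currents shape the ion concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from . import _kernels, _layout as L
from .currents import ConcentrationError
from .model import rhs_reduced
from .parameters import ModelParameters, MutationSpec
from .states import ReducedState


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario description for :func:`integrate`."""

    mode: Literal["coupled", "isolated_interneuron"] = "coupled"
    mutation: MutationSpec = field(default_factory=MutationSpec.wild_type)
    g_D_e: float = 0.0
    g_D_i: float = 0.0
    duration: float = 1000.0        # ms
    dt: float = 0.01                # ms
    record_stride: int = 10
    buffering: Literal["none", "strong_K", "strong_Na"] = "none"
    eps_override: float | None = None
    state_mode: Literal["reduced", "full"] = "reduced"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.mode not in ("coupled", "isolated_interneuron"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.buffering not in ("none", "strong_K", "strong_Na"):
            raise ValueError(f"unknown buffering {self.buffering!r}")


@dataclass
class Trace:
    """Sampled state over time.  ``data`` holds one column per variable;
    derived concentrations are included for reduced-state runs."""

    time: np.ndarray                 # ms
    data: pd.DataFrame
    params: ModelParameters
    mode: str

    def __len__(self) -> int:
        return len(self.time)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "time_ms", self.time)
        out.to_csv(path, index=False, float_format="%.10g")


@dataclass
class EventLog:
    """Spike times (ms) per neuron, from upward threshold crossings."""

    pyramidal: np.ndarray
    gabaergic: np.ndarray

    def to_csv(self, path) -> None:
        rows = ([("pyramidal", t) for t in self.pyramidal]
                + [("gabaergic", t) for t in self.gabaergic])
        pd.DataFrame(rows, columns=["neuron", "spike_time_ms"]).to_csv(
            path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Rest state
# ---------------------------------------------------------------------------

STRONG_BUFFER_RATE = 0.1  # 1/ms, for the strong_K / strong_Na perturbations

_REST_CACHE: dict[bytes, ReducedState] = {}
_ISO_REST_CACHE: dict[bytes, ReducedState] = {}


def standard_state(params: ModelParameters) -> ReducedState:
    """The standard resting configuration used as protocol initial condition.

    Concentrations sit at the physiological reference values that pin the
    first integrals (intracellular Na+/K+ = 10/140 mM in both cells,
    pyramidal Cl- = 5 mM, extracellular K+ = 3.5 mM); gating variables are
    at their steady state for -70 mV, calcium and synaptic variables at
    zero.  In the absence of external drive this configuration is
    stationary on the sub-second timescale of an action-potential protocol
    (the residual intracellular-sodium drift is ~0.25 mM/s); the exact
    equilibrium of the system is available via :func:`find_rest_state` as
    a cross-validation mode.
    """
    from .currents import interneuron_gating, pyramidal_gating_rates

    am, bm, ah, bh, an, bn = pyramidal_gating_rates(-70.0)
    _, h_inf, _, n_inf, _ = interneuron_gating(-70.0)
    return ReducedState(
        v_e=-70.0, m_e=float(am / (am + bm)), h_e=float(ah / (ah + bh)),
        n_e=float(an / (an + bn)), Na_e=10.0, Cl_e=5.0, Ca_e=0.0, s_e=0.0,
        v_i=-70.0, h_i=float(h_inf), n_i=float(n_inf), Na_i=10.0, s_i=0.0,
        K_o=3.5)


# Backwards-compatible alias: the standard state is the reference point of
# the conserved-quantity bookkeeping.
reference_state = standard_state


def find_rest_state(params: ModelParameters, *, max_relax_s: float = 200.0,
                    tol: float = 1e-9) -> ReducedState:
    """Steady state of the coupled system in the absence of external drive.

    Relaxes from the reference point with both drives at zero, then
    polishes the equilibrium with a damped Newton solve of the reduced
    right-hand side; the result satisfies ``max |dy/dt| < tol``.
    """
    from scipy.optimize import root

    p_rest = params.with_drives(0.0, 0.0)
    key = p_rest.to_array().tobytes()
    if key in _REST_CACHE:
        return _REST_CACHE[key]

    parr = p_rest.to_array()
    y = reference_state(p_rest).to_array()
    dt = 0.05
    relaxed_s = 0.0
    chunk_s = 20.0

    def residual(yv: np.ndarray) -> np.ndarray:
        return rhs_reduced(yv, p_rest)

    rest = None
    while relaxed_s <= max_relax_s:
        status, _, Y, n_rec, *_ = _kernels.integrate_reduced(
            y, parr, dt, int(chunk_s * 1000.0 / dt), 1000)
        if status != 0:
            raise IntegrationError(
                "relaxation towards rest failed (non-finite state)")
        y = Y[n_rec - 1].copy()
        relaxed_s += chunk_s
        sol = root(residual, y, method="hybr", tol=1e-13)
        res = residual(sol.x)
        if np.max(np.abs(res)) < tol:
            rest = sol.x
            break
    if rest is None:
        raise IntegrationError(
            f"rest state did not converge: residual max-norm "
            f"{np.max(np.abs(residual(y))):.3e} after {relaxed_s:.0f} s")
    state = ReducedState.from_array(rest)
    _REST_CACHE[key] = state
    return state


def find_isolated_rest_state(params: ModelParameters, *,
                             tol: float = 1e-9) -> ReducedState:
    """Rest state of the isolated-interneuron system (drive at zero).

    The pyramidal cell is frozen at the standard configuration
    ([Na+]_e = 10 mM); the six interneuron variables are relaxed from the
    standard state and polished to an equilibrium with ``max |dy/dt| <
    tol``.  Returned as a :class:`ReducedState` whose pyramidal fields
    hold the frozen values.
    """
    from scipy.optimize import root

    p_rest = params.with_drives(0.0, 0.0)
    key = p_rest.to_array().tobytes()
    if key in _ISO_REST_CACHE:
        return _ISO_REST_CACHE[key]

    std = standard_state(p_rest)
    parr = p_rest.to_array()
    na_e_frozen = std.Na_e
    y0 = np.array([std.v_i, std.h_i, std.n_i, std.Na_i, std.s_i, std.K_o])
    dt = 0.05
    status, _, Y, n_rec, *_ = _kernels.integrate_isolated(
        y0, parr, na_e_frozen, dt, int(60_000.0 / dt), 10_000)
    if status != 0:
        raise IntegrationError("isolated rest relaxation failed")

    dy = np.empty(L.N_ISOLATED)

    def residual(yv: np.ndarray) -> np.ndarray:
        _kernels.rhs_isolated(yv, parr, na_e_frozen, dy)
        return dy.copy()

    sol = root(residual, Y[n_rec - 1], method="hybr", tol=1e-13)
    if np.max(np.abs(residual(sol.x))) >= tol:
        raise IntegrationError(
            f"isolated rest did not converge: residual "
            f"{np.max(np.abs(residual(sol.x))):.3e}")
    v_i, h_i, n_i, na_i, s_i, k_o = sol.x
    state = replace(std, v_i=float(v_i), h_i=float(h_i), n_i=float(n_i),
                    Na_i=float(na_i), s_i=float(s_i), K_o=float(k_o))
    _ISO_REST_CACHE[key] = state
    return state


# ---------------------------------------------------------------------------
# Scenario assembly and integration
# ---------------------------------------------------------------------------

def _effective_parameters(config: SimulationConfig,
                          base: ModelParameters | None = None
                          ) -> ModelParameters:
    """Apply the mutation transform, drives and potassium-side buffering."""
    params = (base or ModelParameters()).with_mutation(config.mutation)
    if config.eps_override is not None:
        params = replace(params, bath=replace(params.bath,
                                              eps_K=config.eps_override))
    if config.buffering == "strong_K":
        params = replace(params, bath=replace(params.bath,
                                              eps_K=STRONG_BUFFER_RATE))
    return params.with_drives(config.g_D_e, config.g_D_i)


def _check_status(status: int, t_last: float) -> None:
    if status == 1:
        raise IntegrationError(
            f"non-finite state at t = {t_last:.3f} ms; last valid time "
            f"{t_last:.3f} ms")
    if status == 2:
        raise ConcentrationError(
            f"non-positive concentration at t = {t_last:.3f} ms")


def _reduced_frame(Y: np.ndarray, params: ModelParameters) -> pd.DataFrame:
    df = pd.DataFrame(Y, columns=list(L.REDUCED_NAMES))
    g, t = params.geometry, params.totals
    cm = params.constants.C_m
    df["K_e"] = g.gamma_e * (cm * df["v_e"] - t.H1) - df["Na_e"] + df["Cl_e"]
    df["K_i"] = g.gamma_i * (cm * df["v_i"] - t.H2) - df["Na_i"]
    df["Na_o"] = t.Na_sum - g.vol_frac_e * df["Na_e"] - g.vol_frac_i * df["Na_i"]
    df["Cl_o"] = t.Cl_sum - g.vol_frac_e * df["Cl_e"]
    return df


def integrate(config: SimulationConfig,
              init: ReducedState | None = None,
              base_params: ModelParameters | None = None
              ) -> tuple[Trace, EventLog]:
    """Simulate a scenario and return the sampled trace plus spike log.

    The initial condition defaults to the standard resting configuration
    for coupled runs and to the converged isolated rest state for
    isolated-interneuron runs.  For ``strong_Na`` buffering, sodium mass
    conservation is broken by the bath-exchange term, so the full
    18-variable state is integrated regardless of ``state_mode``.
    """
    params = _effective_parameters(config, base_params)
    if init is None:
        if config.mode == "isolated_interneuron":
            init = find_isolated_rest_state(params)
        else:
            init = standard_state(params)
    if config.buffering == "strong_Na":
        params = replace(params, bath=replace(
            params.bath, eps_Na=STRONG_BUFFER_RATE,
            Na_bath=init.Na_o(params)))
    n_steps = int(round(config.duration / config.dt))
    stride = config.record_stride
    parr = params.to_array()

    if config.mode == "isolated_interneuron":
        y0 = np.array([init.v_i, init.h_i, init.n_i, init.Na_i, init.s_i,
                       init.K_o])
        status, t_last, Y, n_rec, spk_i, n_spk_i = _kernels.integrate_isolated(
            y0, parr, init.Na_e, config.dt, n_steps, stride)
        _check_status(status, t_last)
        Y = Y[:n_rec]
        df = pd.DataFrame(Y, columns=list(L.ISOLATED_NAMES))
        g, t = params.geometry, params.totals
        df["K_i"] = (g.gamma_i * (params.constants.C_m * df["v_i"] - t.H2)
                     - df["Na_i"])
        df["Na_o"] = (t.Na_sum - g.vol_frac_e * init.Na_e
                      - g.vol_frac_i * df["Na_i"])
        events = EventLog(pyramidal=np.empty(0),
                          gabaergic=spk_i[:n_spk_i].copy())
    elif config.state_mode == "full" or config.buffering == "strong_Na":
        y0 = init.lift(params).to_array()
        status, t_last, Y, n_rec, spk_e, n_spk_e, spk_i, n_spk_i = \
            _kernels.integrate_full(y0, parr, config.dt, n_steps, stride)
        _check_status(status, t_last)
        df = pd.DataFrame(Y[:n_rec], columns=list(L.FULL_NAMES))
        events = EventLog(pyramidal=spk_e[:n_spk_e].copy(),
                          gabaergic=spk_i[:n_spk_i].copy())
    else:
        y0 = init.to_array()
        status, t_last, Y, n_rec, spk_e, n_spk_e, spk_i, n_spk_i = \
            _kernels.integrate_reduced(y0, parr, config.dt, n_steps, stride)
        _check_status(status, t_last)
        df = _reduced_frame(Y[:n_rec], params)
        events = EventLog(pyramidal=spk_e[:n_spk_e].copy(),
                          gabaergic=spk_i[:n_spk_i].copy())

    time = np.arange(len(df)) * config.dt * stride
    return Trace(time=time, data=df, params=params, mode=config.mode), events
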