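"""Slow-fast dissection of the isolated fast-spiking interneuron.

During sustained stimulation the interneuron's intracellular sodium
[Na+]_i varies far more slowly than its voltage and gating variables.
Treating [Na+]_i as a frozen parameter yields a three-variable *fast
subsystem* (v_i, h_i, n_i) whose bifurcation structure explains the
full system's behaviour: large-amplitude limit cycles (repetitive
firing) terminate at a fold of limit cycles as [Na+]_i grows, forcing a
jump to a coexisting depolarized steady state; in the wild type a
subcritical Hopf bifurcation at lower [Na+]_i destabilizes that state
again, closing a hysteresis loop that produces bursting, whereas the
loss-of-function variant lacks the hysteresis and remains in permanent
depolarization block.

The non-clamped concentrations are frozen: [K+]_o and [Na+]_o at their
values on the full trajectory at the onset of firing (configurable), and
[K+]_i derived from the H2 first integral at the instantaneous voltage,
which keeps that constraint exact while [Na+]_i alone plays the role of
the slow variable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import root

from . import _kernels
from .currents import interneuron_gating
from .parameters import ModelParameters, MutationSpec
from .simulator import EventLog, Trace

CYCLE_DETECT_V = -20.0   # mV, upward-crossing level for period detection


@dataclass(frozen=True)
class FastSubsystemSpec:
    """Fast subsystem (v_i, h_i, n_i) with [Na+]_i clamped.

    ``K_o``/``Na_o`` form the frozen extracellular context; the drive and
    mutation determine the interneuron parameters.  There is no synaptic
    input (isolated interneuron) and s_i plays no role (no autapse).
    """

    Na_i: float
    K_o: float
    Na_o: float
    g_D_i: float = 0.3
    mutation: MutationSpec = MutationSpec.wild_type()
    base_params: ModelParameters | None = None

    def params(self) -> ModelParameters:
        base = self.base_params or ModelParameters()
        return base.with_mutation(self.mutation).with_drives(None, self.g_D_i)

    def param_array(self) -> np.ndarray:
        return self.params().to_array()

    def with_Na_i(self, Na_i: float) -> "FastSubsystemSpec":
        return replace(self, Na_i=Na_i)


import functools


@functools.lru_cache(maxsize=16)
def default_context(mutation: MutationSpec = MutationSpec.wild_type(),
                    g_D_i: float = 0.3, duration_ms: float = 60_000.0,
                    base_params: ModelParameters | None = None
                    ) -> FastSubsystemSpec:
    """Frozen-context spec taken from the full isolated trajectory at the
    onset of its first quiescent (depolarization-block) phase.

    The slow variable [Na+]_i reaches the fold of cycles exactly when the
    active phase ends, so freezing [K+]_o and [Na+]_o there makes the
    one-parameter diagram self-consistent with the trajectory it is meant
    to explain.  Falls back to the point of maximal [Na+]_i when no
    quiescent phase occurs within ``duration_ms``.
    """
    from .protocols import detect_depolarization_block
    from .simulator import SimulationConfig, integrate

    cfg = SimulationConfig(mode="isolated_interneuron", mutation=mutation,
                           g_D_i=g_D_i, duration=duration_ms,
                           record_stride=10)
    trace, _ = integrate(cfg, base_params=base_params)
    block = detect_depolarization_block(trace, "gabaergic")
    if block is not None:
        idx = int(np.searchsorted(trace.time, block.onset_ms))
    else:
        idx = int(np.argmax(trace["Na_i"]))
    idx = min(idx, len(trace) - 1)
    return FastSubsystemSpec(
        Na_i=float(trace["Na_i"][idx]), K_o=float(trace["K_o"][idx]),
        Na_o=float(trace["Na_o"][idx]), g_D_i=g_D_i, mutation=mutation,
        base_params=base_params)


def fast_rhs(state, spec: FastSubsystemSpec) -> np.ndarray:
    """Time derivative of (v_i, h_i, n_i) with the frozen context."""
    y = np.asarray(state, dtype=float)
    dv, dh, dn = _kernels.rhs_fast(y, spec.param_array(), spec.Na_i,
                                   spec.K_o, spec.Na_o)
    return np.array([dv, dh, dn])


def _jacobian(y: np.ndarray, spec: FastSubsystemSpec,
              h: float = 1e-6) -> np.ndarray:
    J = np.empty((3, 3))
    for j in range(3):
        step = h * max(1.0, abs(y[j]))
        yp = y.copy()
        ym = y.copy()
        yp[j] += step
        ym[j] -= step
        J[:, j] = (fast_rhs(yp, spec) - fast_rhs(ym, spec)) / (2.0 * step)
    return J


@dataclass(frozen=True)
class Equilibrium:
    v_i: float
    h_i: float
    n_i: float
    stable: bool
    eigenvalues: tuple[complex, complex, complex]


def find_equilibria(spec: FastSubsystemSpec,
                    v_seeds: np.ndarray | None = None,
                    tol: float = 1e-8) -> list[Equilibrium]:
    """Equilibria of the fast subsystem by multi-start root finding.

    Seeds sweep v_i over [-90, 0] mV with h, n at their steady-state
    values; duplicates are merged at 1e-6; stability comes from the
    eigenvalues of a central-difference Jacobian.
    """
    if v_seeds is None:
        v_seeds = np.linspace(-90.0, 0.0, 31)
    found: list[np.ndarray] = []
    for v0 in v_seeds:
        _, h_inf, _, n_inf, _ = interneuron_gating(v0)
        sol = root(lambda y: fast_rhs(y, spec),
                   np.array([v0, float(h_inf), float(n_inf)]),
                   method="hybr", tol=1e-12)
        if not sol.success:
            continue
        y = sol.x
        if np.max(np.abs(fast_rhs(y, spec))) > tol:
            continue
        if not (0.0 <= y[1] <= 1.0 and 0.0 <= y[2] <= 1.0):
            continue
        if any(np.max(np.abs(y - f) / np.array([1.0, 1e-2, 1e-2]))
               < 1e-4 for f in found):
            continue
        found.append(y)
    out = []
    for y in sorted(found, key=lambda q: q[0]):
        eig = np.linalg.eigvals(_jacobian(y, spec))
        out.append(Equilibrium(
            v_i=float(y[0]), h_i=float(y[1]), n_i=float(y[2]),
            stable=bool(np.max(eig.real) < 0.0),
            eigenvalues=tuple(eig)))
    return out


@dataclass(frozen=True)
class CycleSummary:
    v_min: float
    v_max: float
    period_ms: float


def find_limit_cycle(spec: FastSubsystemSpec, transient_ms: float = 500.0,
                     observe_ms: float = 1500.0, dt: float = 0.01
                     ) -> CycleSummary | None:
    """Detect a stable spiking limit cycle by direct simulation.

    Integrates from a spiking-phase seed, discards a transient, then
    measures the period from successive upward crossings of -20 mV.
    Returns ``None`` when the trajectory settles onto an equilibrium.
    """
    _, h_inf, _, n_inf, _ = interneuron_gating(-60.0)
    y0 = np.array([-60.0, float(h_inf), float(n_inf)])
    n_trans = int(round(transient_ms / dt))
    n_obs = int(round(observe_ms / dt))
    parr = spec.param_array()
    Y, n = _kernels.integrate_fast(y0, parr, spec.Na_i, spec.K_o, spec.Na_o,
                                   dt, n_trans + n_obs, 1)
    v = Y[n_trans:n, 0]
    if v.max() - v.min() < 1.0:       # converged to a steady state
        return None
    up = np.flatnonzero((v[:-1] < CYCLE_DETECT_V) & (v[1:] >= CYCLE_DETECT_V))
    if len(up) < 3:
        return None
    periods = np.diff(up).astype(float) * dt
    # steady periodicity: last periods must agree
    if len(periods) >= 2 and abs(periods[-1] - periods[-2]) > 0.05 * periods[-1]:
        return None
    last = up[-2], up[-1]
    seg = v[last[0]:last[1] + 1]
    return CycleSummary(v_min=float(seg.min()), v_max=float(seg.max()),
                       period_ms=float(periods[-1]))


def locate_fold_of_cycles(spec: FastSubsystemSpec, Na_lo: float = 15.0,
                          Na_hi: float = 40.0, tol: float = 0.05) -> float:
    """[Na+]_i at which the spiking limit cycle disappears (fold of
    cycles), by bisection on the cycle-existence predicate."""
    def has_cycle(na: float) -> bool:
        return find_limit_cycle(spec.with_Na_i(na)) is not None

    if not has_cycle(Na_lo):
        raise ValueError(f"no limit cycle at the low end Na_i = {Na_lo}")
    if has_cycle(Na_hi):
        raise ValueError(f"limit cycle persists at the high end Na_i = {Na_hi}")
    lo, hi = Na_lo, Na_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_cycle(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def locate_hopf(spec: FastSubsystemSpec, Na_lo: float = 5.0,
                Na_hi: float = 40.0, tol: float = 0.05) -> float | None:
    """[Na+]_i at which the depolarized steady state changes stability
    (Hopf bifurcation), by bisection on the sign of the largest
    eigenvalue real part along the upper equilibrium branch."""
    def max_real(na: float) -> float | None:
        eqs = find_equilibria(spec.with_Na_i(na))
        if not eqs:
            return None
        eq = eqs[-1]  # most depolarized branch
        return max(ev.real for ev in eq.eigenvalues)

    r_lo, r_hi = max_real(Na_lo), max_real(Na_hi)
    if r_lo is None or r_hi is None or (r_lo < 0) == (r_hi < 0):
        return None
    lo, hi = Na_lo, Na_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        r = max_real(mid)
        if r is None:
            return None
        if (r < 0) == (r_hi < 0):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class BranchData:
    """One-parameter bifurcation diagram of the fast subsystem vs [Na+]_i."""

    table: pd.DataFrame          # per grid point: equilibria and cycle data
    fold_of_cycles: float | None
    hopf: float | None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def branch_data(spec: FastSubsystemSpec, Na_grid=None) -> BranchData:
    """Sweep [Na+]_i, collecting equilibria, stability, and limit-cycle
    extent/period, plus the located fold-of-cycles and Hopf points."""
    if Na_grid is None:
        Na_grid = np.arange(5.0, 40.0 + 1e-9, 1.0)
    rows = []
    for na in Na_grid:
        sp = spec.with_Na_i(float(na))
        cyc = find_limit_cycle(sp)
        for eq in find_equilibria(sp):
            rows.append({
                "Na_i": na, "eq_v_i": eq.v_i, "stable": eq.stable,
                "cycle_v_min": np.nan if cyc is None else cyc.v_min,
                "cycle_v_max": np.nan if cyc is None else cyc.v_max,
                "cycle_period_ms": np.nan if cyc is None else cyc.period_ms})
    df = pd.DataFrame(rows)
    has = df.groupby("Na_i")["cycle_period_ms"].apply(
        lambda s: s.notna().any())
    fold = hopf = None
    try:
        lo_candidates = [na for na, h in has.items() if h]
        hi_candidates = [na for na, h in has.items() if not h
                         and lo_candidates and na > max(lo_candidates)]
        if lo_candidates and hi_candidates:
            fold = locate_fold_of_cycles(spec, max(lo_candidates),
                                         min(hi_candidates))
    except ValueError:
        fold = None
    hopf = locate_hopf(spec, float(Na_grid[0]), float(Na_grid[-1]))
    return BranchData(table=df, fold_of_cycles=fold, hopf=hopf)


def dissection_overlay(trace: Trace) -> pd.DataFrame:
    """Project a full isolated-interneuron trajectory onto the
    ([Na+]_i, v_i) plane for superposition on the bifurcation diagram."""
    return pd.DataFrame({"Na_i": trace["Na_i"], "v_i": trace["v_i"]})
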