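"""Scenario configuration files, deterministic artifact serialization and
fixture generation.

A scenario file is a flat YAML mapping; unknown keys are rejected so that
configuration drift is caught early.  The whole pipeline is deterministic:
rerunning a scenario with an identical configuration reproduces every
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd
import yaml

from .parameters import ModelParameters, MutationSpec
from .simulator import SimulationConfig, integrate


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one simulation scenario."""

    name: str = "scenario"
    mode: str = "coupled"
    mutation_variant: str = "wild_type"
    p_Na_P: float = 0.0
    conductance_scale: float = 1.0
    g_D_e: float = 0.0
    g_D_i: float = 0.0
    duration_ms: float = 1000.0
    dt_ms: float = 0.01
    record_stride: int = 10
    buffering: str = "none"
    eps_override: float | None = None
    state_mode: str = "reduced"

    def mutation(self) -> MutationSpec:
        if self.mutation_variant == "fhm3":
            return MutationSpec.fhm3(self.p_Na_P)
        if self.mutation_variant == "epileptogenic":
            return MutationSpec.epileptogenic(self.conductance_scale)
        return MutationSpec.wild_type()

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(
            mode=self.mode, mutation=self.mutation(), g_D_e=self.g_D_e,
            g_D_i=self.g_D_i, duration=self.duration_ms, dt=self.dt_ms,
            record_stride=self.record_stride, buffering=self.buffering,
            eps_override=self.eps_override, state_mode=self.state_mode)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if d["eps_override"] is None:
            del d["eps_override"]
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @staticmethod
    def from_dict(data: dict) -> "ScenarioConfig":
        known = {f.name for f in fields(ScenarioConfig)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown scenario keys: {sorted(unknown)}")
        return ScenarioConfig(**data)

    @staticmethod
    def load(source: Union[str, Path, IO[str]]) -> "ScenarioConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("scenario file must contain a mapping")
        return ScenarioConfig.from_dict(data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def run_scenario(config: ScenarioConfig, out_dir,
                 base_params: ModelParameters | None = None) -> dict:
    """Simulate one scenario and write trace/event/summary CSVs plus a log.

    Returns a dict with the paths written and the summary row.
    """
    from .protocols import count_overshooting_spikes, detect_depolarization_block

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.perf_counter()
    sim = config.simulation()
    trace, events = integrate(sim, base_params=base_params)
    wall = _time.perf_counter() - t0

    trace_path = out / f"{config.name}_trace.csv"
    events_path = out / f"{config.name}_events.csv"
    summary_path = out / f"{config.name}_summary.csv"
    log_path = out / f"{config.name}.log"

    trace.to_csv(trace_path)
    events.to_csv(events_path)

    summary: dict[str, object] = {
        "scenario": config.name,
        "config_digest": config.digest(),
        "dt_ms": config.dt_ms,
        "duration_ms": config.duration_ms,
        "n_samples": len(trace),
        "gabaergic_spikes": len(events.gabaergic),
        "K_o_end_mM": round(float(trace["K_o"][-1]), 6),
        "Na_o_end_mM": round(float(trace["Na_o"][-1]), 6),
    }
    if config.mode == "coupled":
        summary["pyramidal_spikes"] = len(events.pyramidal)
        if config.duration_ms >= 500.0:
            for neuron in ("pyramidal", "gabaergic"):
                blk = detect_depolarization_block(trace, neuron)
                summary[f"{neuron}_block_onset_ms"] = (
                    "" if blk is None else round(blk.onset_ms, 3))
    if config.duration_ms > 0:
        summary["overshooting_spikes"] = count_overshooting_spikes(
            trace, "gabaergic")
    pd.DataFrame([summary]).to_csv(summary_path, index=False)

    params = (base_params or ModelParameters()).with_mutation(
        config.mutation())
    defaults = ModelParameters().to_flat_dict()
    overrides = {k: v for k, v in params.to_flat_dict().items()
                 if defaults.get(k) != v}
    with open(log_path, "w") as fh:
        fh.write(f"scenario: {config.name}\n")
        fh.write(f"config:\n{config.to_yaml()}")
        fh.write(f"mutation transform applied: {config.mutation()}\n")
        fh.write("parameters (non-default):\n")
        for k, v in sorted(overrides.items()):
            fh.write(f"  {k}: {v!r}  (default {defaults.get(k)!r})\n")
        fh.write(f"solver: RK4 fixed step dt = {config.dt_ms} ms\n")
        fh.write(f"wall_time_s: {wall:.3f}\n")
    return {"trace": trace_path, "events": events_path,
            "summary": summary_path, "log": log_path, "row": summary}


# ---------------------------------------------------------------------------
# Regression fixtures
# ---------------------------------------------------------------------------

HEADLINE_SCENARIOS: tuple[ScenarioConfig, ...] = (
    ScenarioConfig(name="coupled_wild_type", mode="coupled",
                   g_D_e=0.3, g_D_i=0.3, duration_ms=30_000.0),
    ScenarioConfig(name="coupled_fhm3_15", mode="coupled",
                   mutation_variant="fhm3", p_Na_P=15.0,
                   g_D_e=0.3, g_D_i=0.3, duration_ms=30_000.0),
    ScenarioConfig(name="coupled_epileptogenic", mode="coupled",
                   mutation_variant="epileptogenic", conductance_scale=0.4,
                   g_D_e=0.3, g_D_i=0.3, duration_ms=30_000.0),
    ScenarioConfig(name="isolated_p0", mode="isolated_interneuron",
                   g_D_i=0.3, duration_ms=400.0),
    ScenarioConfig(name="isolated_p20", mode="isolated_interneuron",
                   mutation_variant="fhm3", p_Na_P=20.0,
                   g_D_i=0.3, duration_ms=400.0),
)


def generate_fixtures(out_dir, *, quick: bool = False) -> dict:
    """Produce the deterministic regression corpus.

    Writes rest states for the three variants, isolated input-output
    grids at p in {0, 10, 20}%, the headline coupled scenarios, and the
    fast-subsystem branch data.  ``quick`` shortens durations and grids
    for test-time use; the artifact remains fully deterministic either
    way.
    """
    from . import slowfast
    from .protocols import io_curve
    from .simulator import find_isolated_rest_state, find_rest_state

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"quick": quick, "entries": []}

    variants = {"wild_type": MutationSpec.wild_type(),
                "fhm3_20": MutationSpec.fhm3(20.0),
                "epileptogenic": MutationSpec.epileptogenic()}
    rest_rows = []
    for name, mut in variants.items():
        params = ModelParameters().with_mutation(mut)
        rest = (find_rest_state(params) if not quick
                else find_isolated_rest_state(params))
        row = {"variant": name, **asdict(rest)}
        rest_rows.append(row)
    pd.DataFrame(rest_rows).to_csv(out / "rest_states.csv", index=False,
                                   float_format="%.12g")
    manifest["entries"].append("rest_states.csv")

    grid = ([0.0, 0.05, 0.3] if quick
            else list(np.round(np.arange(0.0, 0.301, 0.02), 3)))
    duration = 100.0 if quick else 400.0
    for p in (0.0, 10.0, 20.0):
        mut = MutationSpec.fhm3(p) if p else MutationSpec.wild_type()
        curve = io_curve(mut, grid, duration_ms=duration)
        fname = f"io_curve_p{int(p)}.csv"
        curve.to_frame().to_csv(out / fname, index=False,
                                float_format="%.8g")
        manifest["entries"].append(fname)

    for cfg in HEADLINE_SCENARIOS:
        if quick:
            cfg = ScenarioConfig(**{**cfg.to_dict(),
                                    "duration_ms": min(cfg.duration_ms, 500.0)})
        run_scenario(cfg, out)
        manifest["entries"].append(f"{cfg.name}_summary.csv")

    spec = slowfast.default_context(
        MutationSpec.wild_type(), 0.3,
        duration_ms=2000.0 if quick else 60_000.0)
    na_grid = np.arange(20.0, 32.0 + 1e-9, 4.0) if quick else None
    branch = slowfast.branch_data(spec, na_grid)
    branch.to_csv(out / "branch_wild_type.csv")
    manifest["entries"].append("branch_wild_type.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
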