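"""Shared fixtures.

The expensive 30 s coupled simulations and the finely sampled isolated
runs are session-scoped so that property tests and acceptance tests share
one integration each.
"""

from __future__ import annotations

import numpy as np
import pytest

from navmicro import (ModelParameters, MutationSpec, SimulationConfig,
                      integrate)
from navmicro.states import ReducedState


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


def random_reduced_states(n: int, seed: int = 0) -> list[ReducedState]:
    """Physiologically plausible random states (all concentrations valid)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(ReducedState(
            v_e=rng.uniform(-90.0, 30.0),
            m_e=rng.uniform(0.0, 1.0), h_e=rng.uniform(0.0, 1.0),
            n_e=rng.uniform(0.0, 1.0),
            Na_e=rng.uniform(2.0, 30.0), Cl_e=rng.uniform(2.0, 20.0),
            Ca_e=rng.uniform(0.0, 0.01), s_e=rng.uniform(0.0, 1.0),
            v_i=rng.uniform(-90.0, 30.0),
            h_i=rng.uniform(0.0, 1.0), n_i=rng.uniform(0.0, 1.0),
            Na_i=rng.uniform(2.0, 30.0), s_i=rng.uniform(0.0, 1.0),
            K_o=rng.uniform(2.0, 30.0)))
    return out


def _isolated(p_na_p: float):
    mut = MutationSpec.fhm3(p_na_p) if p_na_p else MutationSpec.wild_type()
    cfg = SimulationConfig(mode="isolated_interneuron", mutation=mut,
                           g_D_i=0.3, duration=400.0, dt=0.01,
                           record_stride=1)
    return integrate(cfg)


@pytest.fixture(scope="session")
def iso_run_p0():
    """Isolated interneuron, wild type, 0.4 s at g_D,i = 0.3 (fine sampling)."""
    return _isolated(0.0)


@pytest.fixture(scope="session")
def iso_run_p20():
    """Isolated interneuron, 20% persistent current, same protocol."""
    return _isolated(20.0)


def _coupled(mutation: MutationSpec, duration_ms: float = 30_000.0):
    cfg = SimulationConfig(mode="coupled", mutation=mutation, g_D_e=0.3,
                           g_D_i=0.3, duration=duration_ms, dt=0.01)
    return integrate(cfg)


@pytest.fixture(scope="session")
def coupled_wt():
    """Coupled circuit, wild type, 30 s at g = 0.3."""
    return _coupled(MutationSpec.wild_type())


@pytest.fixture(scope="session")
def coupled_fhm3_15():
    """Coupled circuit, 15% persistent current, 30 s at g = 0.3."""
    return _coupled(MutationSpec.fhm3(15.0))


@pytest.fixture(scope="session")
def coupled_epi():
    """Coupled circuit, epileptogenic variant, 30 s at g = 0.3."""
    return _coupled(MutationSpec.epileptogenic(0.4))
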