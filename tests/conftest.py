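"""Shared fixtures.

The expensive fixtures (equilibrated gels) are session-scoped and shared
across test modules; everything downstream derives its own seeded streams
so tests stay order-independent.
"""

import numpy as np
import pytest
from hypothesis import settings

from nanorelease.builder import build_topology, equilibrate, structure_report
from nanorelease.model import SimulationParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    from nanorelease.model import RNGStream

    return RNGStream(12345)


@pytest.fixture(scope="session")
def small_gel():
    """A quick-to-equilibrate miniature nanogel (~50 crosslinkers)."""
    topo, system = build_topology(60, 4, 48, 2.25)
    params = SimulationParams(mode="flexible", seed=11)
    gel = equilibrate(system, topo, params, window_steps=10_000, tol=0.02,
                      max_windows=20)
    return topo, gel


@pytest.fixture(scope="session")
def reference_gel():
    """The equilibrated reference nanogel (692 tetramer chains, 404
    crosslinkers); shared by the structure, loading and release tests."""
    topo, system = build_topology(692, 4, 404, 2.25)
    params = SimulationParams(mode="flexible", seed=20)
    gel = equilibrate(system, topo, params)
    return topo, gel


@pytest.fixture(scope="session")
def reference_report(reference_gel):
    topo, gel = reference_gel
    return structure_report(gel, topo)
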