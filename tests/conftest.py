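"""Shared fixtures.

The expensive baseline ensemble (4 × 1200 s) is session-scoped and shared
between the firing-statistics, autocorrelation and anticorrelation tests.
"""

import numpy as np
import pytest

from stenpol.core import simulate
from stenpol.meanfield import basal_equilibrium
from stenpol.params import FeedbackSpec, Lattice, ModelSpec, SimSettings


@pytest.fixture(scope="session")
def bare_model():
    return ModelSpec()


@pytest.fixture(scope="session")
def basal_point(bare_model):
    return basal_equilibrium(bare_model)


@pytest.fixture(scope="session")
def baseline_runs(bare_model):
    """Four 1200 s baseline simulations with distinct seeds."""
    return [simulate(bare_model, SimSettings(duration=1200.0, seed=s))
            for s in range(1, 5)]


@pytest.fixture()
def lattice():
    return Lattice()


def short_settings(seed=0, duration=200.0, n_points=126, dx=0.25):
    return SimSettings(duration=duration, seed=seed,
                       lattice=Lattice(n_points=n_points, dx=dx))
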