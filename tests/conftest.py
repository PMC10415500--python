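"""Shared fixtures: simulated patterns and a small featurized pool.

Everything is generated at test time from seeds; the heavier fixtures are
session-scoped so the cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from turingfit import GridSpec, SimulationConfig, gierer_meinhardt, gm_equilibrium, simulate
from turingfit.simulate import SimulationConfig
from turingfit.workbench import FeatureConfig, SweepSpec, featurize_dataset, generate_dataset


@pytest.fixture(scope="session")
def pattern64():
    """One striped/spotted 64x64 steady-state pattern from the c-sweep regime."""
    model = gierer_meinhardt(a=0.02, b=1.0, c=0.5, delta=100.0, s=0.25)
    eq = gm_equilibrium(0.02, 1.0, 0.5)
    return simulate(
        model, GridSpec(64), SimulationConfig(seed=7, t_final=500.0),
        params=dict(a=0.02, b=1.0, c=0.5, delta=100.0, s=0.25),
        u_star=eq.u_star,
    )


@pytest.fixture(scope="session")
def mini_pool():
    """Pool of 30 patterns (c-sweep, 32x32) with RDH features and targets.

    A deliberately scaled-down analogue of the single-parameter study:
    c ~ U[0, 1.15] with a=0.02, b=1, delta=100, s=0.25.
    """
    manifest = generate_dataset(
        SweepSpec.c_sweep(30, n_r=32, base_seed=5), SimulationConfig(t_final=500.0)
    )
    features, targets, r_max = featurize_dataset(manifest, FeatureConfig(radius=8.0))
    return {
        "manifest": manifest,
        "features": features,
        "targets": targets,
        "r_max": r_max,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_bump_histograms(values, bins: int = 12, width: float = 1.2):
    """Synthetic RDH-like histograms: Gaussian bumps whose center moves
    smoothly with a scalar in [0, 1]; an injective, learnable toy map."""
    centers = np.arange(bins)
    X = []
    for v in np.atleast_1d(values):
        h = np.exp(-0.5 * ((centers - v * (bins - 2)) / width) ** 2)
        X.append(h / h.sum())
    return np.array(X)
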