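"""Shared fixtures.

Expensive artefacts (growth runs, elastic fits) are session-scoped so the
suite pays for each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from tipshape import elasticity, geometry, growth, kinematics, synthetic

CELL_RADIUS = 1.75  # micrometre
INC_SIGMA = 1.45  # micrometre; incorporation width used across growth runs


def gaussian_incorporation(s: float) -> float:
    return float(np.exp(-((s / INC_SIGMA) ** 2)))


@pytest.fixture(scope="session")
def scenario():
    return synthetic.SyntheticScenario(seed=11)


@pytest.fixture(scope="session")
def hemisphere_flank():
    return geometry.MeridianContour.hemisphere(CELL_RADIUS, flank=3.0, n=400)


@pytest.fixture(scope="session")
def capsule():
    return geometry.MeridianContour.capsule(CELL_RADIUS, 12.0, n=240)


@pytest.fixture(scope="session")
def selected_params():
    """Material properties selected by the growth-model analysis."""
    return elasticity.ElasticParams(40.0, 0.3)


@pytest.fixture(scope="session")
def shell_fit_params():
    """Material properties from the whole-cell plasmolysis fit."""
    return elasticity.ElasticParams(58.0, 0.033)


@pytest.fixture(scope="session")
def steady_sim(selected_params):
    """Converged growth run from a hemispherical new end (shared)."""
    cap = geometry.MeridianContour.hemisphere(CELL_RADIUS, flank=2.75, n=120)
    sim = growth.simulate_end_evolution(
        cap, gaussian_incorporation, selected_params,
        steps=3000, n_nodes=50, strain_step=0.01, flush_steps=550)
    assert sim.converged
    return sim


@pytest.fixture(scope="session")
def scan_result(selected_params):
    """Material-property scan against a self-generated target (shared)."""
    cap = geometry.MeridianContour.hemisphere(CELL_RADIUS, flank=2.75, n=120)
    kw = dict(steps=2500, n_nodes=45, strain_step=0.012, flush_steps=380)
    target_sim = growth.simulate_end_evolution(
        cap, gaussian_incorporation, selected_params, **kw)
    target = growth.predicted_expansion(target_sim)
    target.band = 0.2 * np.max(target.areal) * np.ones_like(target.areal)
    e_grid = np.array([28.0, 40.0, 57.0])
    nu_grid = np.array([0.05, 0.3, 0.45])
    return growth.material_property_scan(
        target, gaussian_incorporation, e_grid, nu_grid,
        initial_cap=cap, reference=(44.0, -0.06), **kw)


@pytest.fixture(scope="session")
def steady_sim_oe(selected_params):
    """Converged growth run from a pointier, old-end-like cap (shared)."""
    cap = geometry.MeridianContour.spheroid_cap(CELL_RADIUS, aspect=1.6,
                                                flank=1.85, n=120)
    sim = growth.simulate_end_evolution(
        cap, gaussian_incorporation, selected_params,
        steps=3000, n_nodes=50, strain_step=0.01, flush_steps=550)
    assert sim.converged
    return sim
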