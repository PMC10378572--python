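"""Shared fixtures: short synthetic reference signals and steady trajectories.

Session-scoped fixtures cache the expensive simulations (2000-model-unit
steady orbits, reference glottal flows) so that multiple tests can probe the
same trajectory without re-integrating.
"""

import numpy as np
import pytest

from vfokit.model import (FoldGeometry, VFOInitialConditions, VFOParams,
                          glottal_flow, simulate_vfo)


@pytest.fixture(scope="session")
def geom():
    return FoldGeometry()


@pytest.fixture(scope="session")
def ics():
    return VFOInitialConditions(0.01, 0.0, 0.01, 0.0)


@pytest.fixture(scope="session")
def normal_params():
    return VFOParams(0.5, 0.32, 0.0)


@pytest.fixture(scope="session")
def normal_steady_traj(normal_params, ics):
    """Steady orbit at the normal-voice reference point (2000 model units)."""
    return simulate_vfo(normal_params, ics, duration=2000.0, dt=0.02)


@pytest.fixture(scope="session")
def palsy_steady_traj(ics):
    """Steady orbit in the toroidal (vocal-palsy) region."""
    return simulate_vfo(VFOParams(0.4, 0.32, 0.85), ics, duration=2000.0,
                        dt=0.02)


@pytest.fixture(scope="session")
def short_reference_flow(geom, ics):
    """Noiseless reference glottal flow at (0.5, 0.32, 0.2), 30 model units."""
    t = np.linspace(0.0, 30.0, 1501)
    traj = simulate_vfo(VFOParams(0.5, 0.32, 0.2), ics, t_eval=t)
    return glottal_flow(traj, geom)
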