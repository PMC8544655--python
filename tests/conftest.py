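"""Shared fixtures: small simulated acquisitions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from bladerecon.geometry import BladeSpec
from bladerecon.nufft import NufftPlan, density_compensation
from bladerecon.phantom import (
    PhantomSpec,
    SimulationSpec,
    make_coil_profiles,
    make_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def phantom64():
    """Ground-truth phantom and labels at 64^2."""
    return make_phantom(PhantomSpec(matrix_size=64))


@pytest.fixture(scope="session")
def multicoil64(phantom64):
    """Six-coil 20-blade acquisition of the 64^2 phantom (low noise)."""
    truth, labels = phantom64
    maps_true = make_coil_profiles(64, 6, seed=0)
    blade = BladeSpec(128, 9, 20, 64)
    sim = SimulationSpec(blade=blade, n_coils=6, noise_sigma=0.01, seed=0)
    data = simulate_acquisition(truth, maps_true, sim)
    return truth, labels, maps_true, data


@pytest.fixture(scope="session")
def singularity64(phantom64):
    """Same acquisition but coil 1 carries a complex null (phase vortex)."""
    truth, labels = phantom64
    maps_true = make_coil_profiles(64, 6, seed=0, null_in_first_coil=True)
    blade = BladeSpec(128, 9, 20, 64)
    sim = SimulationSpec(blade=blade, n_coils=6, noise_sigma=0.02, seed=0)
    data = simulate_acquisition(truth, maps_true, sim)
    return truth, labels, maps_true, data


@pytest.fixture(scope="session")
def plan_and_weights64(multicoil64):
    _, _, _, data = multicoil64
    plan = NufftPlan(data.traj, 64)
    weights = density_compensation(data.traj, 64, plan=plan)
    return plan, weights


@pytest.fixture(scope="session")
def random_traj():
    """200 random k-space coordinates for operator-level oracles."""
    from bladerecon.geometry import KTrajectory

    rng = np.random.default_rng(7)
    coords = rng.uniform(-np.pi, np.pi, size=(200, 2))
    return KTrajectory(coords, np.zeros(200, int), np.zeros(200, int))
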