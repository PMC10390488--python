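import numpy as np
import pytest

import luadsim as L


@pytest.fixture(scope="session")
def settings():
    """Default model settings (bundled config)."""
    return L.model_settings()


@pytest.fixture(scope="session")
def default_spec():
    return L.vpop_spec()


@pytest.fixture(scope="session")
def small_cohort_outcomes(settings, default_spec):
    """Outcomes of a 250-patient default-population cohort (shared)."""
    patients = L.sample_population(default_spec, 250, seed=20240)
    return L.simulate_cohort(patients, settings)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_radius_trajectory(radii, dt_days=1.0, v_cell=1.0):
    """Single-clone trajectory whose radius follows ``radii`` exactly."""
    r = np.asarray(radii, dtype=float)
    t = np.arange(r.size, dtype=float) * dt_days
    volumes = L.volume_from_radius(r)
    states = np.zeros((r.size, 1, 5))
    states[:, 0, 0] = volumes / v_cell
    return L.TumorTrajectory(t_days=t, states=states, v_cell=v_cell, patient_id="synthetic")
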