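import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qclvcd as q
from qclvcd.simulate import NoiseModel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scaled_cfg():
    """Downscaled narrowband instrument (fast; preserves all ratios)."""
    return q.scaled_test_config()


@pytest.fixture(scope="session")
def full_cfg():
    """Full-scale narrowband instrument (1580-1710 cm^-1, 400 kHz pulses)."""
    return q.narrowband_config()


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel.noiseless()


@pytest.fixture(scope="session")
def fixture_samples():
    return {name: q.protein_fixture(name, 10.0) for name in
            ("bsa", "lysozyme", "beta_lactoglobulin")}


@pytest.fixture(scope="session")
def noiseless_measurements(full_cfg, fixture_samples, noiseless):
    """Full-scale noiseless single-sweep measurements of all three proteins.

    Shared across recovery tests; ~1 s each to compute.
    """
    return {
        name: q.protein_measurement(sample, full_cfg, noiseless, n_scans=1, seed=1)
        for name, sample in fixture_samples.items()
    }


@pytest.fixture
def flat_axis():
    return np.arange(1580.0, 1710.0, 0.5)
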