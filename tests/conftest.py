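import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isoniche import Dataset, IsotopeRecord, MCMCConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(i, group="fish", guild="predator", year=2014, d13C=-25.0, d15N=8.0):
    return IsotopeRecord(f"r{i}", group, guild, year, d13C, d15N)


@pytest.fixture
def simple_dataset():
    """2 consumer groups x 1 year plus baseline, hand-set values."""
    recs = [
        make_record(0, "perch", "predator", 2014, -30.0, 10.0),
        make_record(1, "perch", "predator", 2014, -25.0, 11.0),
        make_record(2, "roach", "omnivore", 2014, -20.0, 7.0),
        make_record(3, "base0", "baseline", 2014, -27.0, 4.0),
        make_record(4, "base1", "baseline", 2014, -27.5, 6.0),
    ]
    return Dataset(records=recs, provenance="fixture")


@pytest.fixture
def fast_mcmc():
    """Reduced sampler settings for unit tests."""
    return MCMCConfig(n_chains=3, n_iter=2_000, burn_in=200, thin=5, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20140805)
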