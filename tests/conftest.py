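import numpy as np
import pandas as pd
import pytest

from epiclonal.config import SimConfig
from epiclonal.simulate import simulate_sites, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast study: 12 donors at 6 sites, 2 combos x 20 loci, 4 ramets,
    4 observation days."""
    return SimConfig(
        n_sites=6, trees_per_site=2, n_primer_combos=2, loci_per_combo=20,
        error_rate_per_combo=(0.01, 0.02), n_replicate_pairs=4,
        ramets_per_donor=4, obs_days=(225, 235, 245, 255), seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def noiseless_config() -> SimConfig:
    """No technical noise, no double absence: scoring must round-trip."""
    return SimConfig(
        n_sites=4, trees_per_site=3, n_primer_combos=2, loci_per_combo=25,
        error_rate_per_combo=(0.0, 0.0), double_absence_rate=0.0,
        ssr_error_rate=0.0, n_replicate_pairs=3, ramets_per_donor=3,
        obs_days=(225, 240, 255), seed=7)


@pytest.fixture(scope="session")
def sites_default():
    return simulate_sites(SimConfig(seed=1, n_sites=10))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
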