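import numpy as np
import pytest

import foxabc
from foxabc.landscape import LandscapeConfig, generate_synthetic_landscape

# miniature inference problem: small coarse landscape, short horizon,
# strongly observable true parameters -- used by the sampler validation
# tests where the full-size problem would be needlessly slow
MINI_CONFIG = LandscapeConfig(
    target_suitable_cells=150,
    suitable_fraction=0.6,
    n_rows=30,
    n_cols=30,
    n_roads=1,
    release_spacing_km=25.0,
)
# true parameters sit in the prior bulk so that recovery/coverage
# experiments are meaningful (a truth far in a prior tail cannot be
# covered by any correctly calibrated ABC posterior)
MINI_TRUTH = foxabc.Theta(
    t0=1998,
    setbacks=(5.0, 5.0, 5.0),
    kernel="invasion",
    q=0.75,
    lam=0.8,
    p_road=0.12,
    p_hunt=0.10,
)
MINI_END_YEAR = 2005
MINI_DATA_SEED = 21


@pytest.fixture(scope="session")
def ref_landscape():
    return foxabc.make_reference_landscape()


@pytest.fixture(scope="session")
def tas_obs():
    return foxabc.observed_tasmanian_data()


@pytest.fixture(scope="session")
def priors():
    return foxabc.Priors()


@pytest.fixture(scope="session")
def mini_landscape():
    return generate_synthetic_landscape(MINI_CONFIG, seed=42)


@pytest.fixture(scope="session")
def mini_observed(mini_landscape):
    """A simulated carcass record from MINI_TRUTH, padded to 1995."""
    series, _ = foxabc.generate_dataset(
        MINI_TRUTH, mini_landscape, MINI_END_YEAR, seed=MINI_DATA_SEED
    )
    n = MINI_END_YEAR - 1995 + 1
    road = np.zeros(n, dtype=int)
    hunt = np.zeros(n, dtype=int)
    i = series.first_year - 1995
    road[i:] = series.road_counts
    hunt[i:] = series.hunter_counts
    return foxabc.CarcassSeries(1995, MINI_END_YEAR, road, hunt)


@pytest.fixture(scope="session")
def mini_prior_population(mini_landscape, priors):
    """Prior draws with attached trajectories (an unconditioned population),
    cheap input for summarization / reweighting tests."""
    rng = np.random.default_rng(77)
    particles, trajectories = [], []
    for _ in range(300):
        th = priors.sample(rng)
        trajectories.append(
            foxabc.simulate_trajectory(th, mini_landscape, 2013, rng)
        )
        particles.append(th)
    return foxabc.ParticlePopulation(
        particles=particles,
        weights=np.full(300, 1 / 300),
        trajectories=trajectories,
        generation=0,
        tolerances=(np.inf, np.inf),
    )
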