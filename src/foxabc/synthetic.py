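"""Synthetic fixtures: the reference landscape and known-parameter datasets.

Everything the pipeline needs is generated programmatically so the full
analysis is reproducible with no external downloads: a canonical
Tasmania-like landscape (fixed seed, exactly 1256 suitable cells, sparse
major roads, three release regions with support at every road-setback
bin), simulated carcass datasets from known parameters for recovery
studies, and the observed Tasmanian record re-exported from the
observation module.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .landscape import Landscape, LandscapeConfig, generate_synthetic_landscape
from .observation import CarcassSeries, extract_carcass_series, observed_tasmanian_data
from .priors import Theta
from .simulate import Trajectory, simulate_trajectory

#: seed of the canonical packaged landscape
REFERENCE_SEED = 20150120


@lru_cache(maxsize=4)
def make_reference_landscape(seed: int = REFERENCE_SEED) -> Landscape:
    """The canonical synthetic landscape (deterministic given the seed)."""
    return generate_synthetic_landscape(LandscapeConfig(), seed=seed)


def generate_dataset(
    theta_true: Theta,
    landscape: Landscape,
    end_year: int,
    seed: int,
) -> tuple[CarcassSeries, Trajectory]:
    """Simulate one dataset from known parameters.

    Returns the observable carcass series (over [t0, end_year]) and the
    latent trajectory (ground truth for recovery tests; withheld from
    inference).
    """
    if not theta_true.in_support():
        raise ValueError("theta_true outside the prior support")
    rng = np.random.default_rng(seed)
    traj = simulate_trajectory(theta_true, landscape, end_year, rng)
    series = extract_carcass_series(traj, theta_true.t0, end_year)
    return series, traj


def tasmanian_fixture() -> CarcassSeries:
    """The observed Tasmanian carcass record (single source of truth)."""
    return observed_tasmanian_data()
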