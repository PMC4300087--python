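"""Prior and posterior predictive distributions of carcass counts.

A predictive draw samples a parameter vector (from the prior, or from the
weighted accepted population), runs a fresh simulation through the end of
the observation window, and records the resulting yearly carcass series.
Unlike the accepted trajectories, posterior predictive draws are NOT
forced to match the observed record — they carry fresh observation noise,
which is what makes them a model-fit check.  Consistency is assessed with
empirical highest-density regions (HDRs) on pairwise count summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import Landscape
from .observation import OBS_FIRST_YEAR, CarcassSeries, extract_carcass_series
from .priors import Priors
from .simulate import simulate_trajectory
from .smc import ParticlePopulation


def predictive_draws(
    source: Priors | ParticlePopulation,
    landscape: Landscape,
    n_draws: int,
    rng: np.random.Generator,
    end_year: int = 2013,
) -> list[CarcassSeries]:
    """Independent draws from the prior or posterior predictive."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    is_population = hasattr(source, "particles")
    out = []
    for _ in range(n_draws):
        if is_population:
            theta = source.particles[source.resample_index(rng)]
        else:
            theta = source.sample(rng)
        traj = simulate_trajectory(
            theta, landscape, end_year, rng,
            record_occupancy=False, record_events=False,
        )
        out.append(
            extract_carcass_series(traj, OBS_FIRST_YEAR, end_year)
        )
    return out


def draws_to_frame(draws: list[CarcassSeries]) -> pd.DataFrame:
    """Long-format table (draw_id, year, road_count, hunter_count)."""
    frames = []
    for i, s in enumerate(draws):
        f = s.to_frame()
        f.insert(0, "draw_id", i)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


@dataclass
class HDRRegion:
    """Empirical 2-D highest-density region on integer count summaries.

    Estimated by ranking cells of a smoothed 2-D histogram of the draws and
    keeping the smallest set of cells holding ``level`` probability mass.
    """

    level: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    member_mask: np.ndarray

    def contains(self, x: float, y: float) -> bool:
        i = np.searchsorted(self.x_edges, x, side="right") - 1
        j = np.searchsorted(self.y_edges, y, side="right") - 1
        if not (0 <= i < self.member_mask.shape[0]):
            return False
        if not (0 <= j < self.member_mask.shape[1]):
            return False
        return bool(self.member_mask[i, j])


def hdr_region(
    draws: list[CarcassSeries],
    level: float = 0.99,
    summary: str = "totals",
    smooth_sigma: float = 0.75,
) -> HDRRegion:
    """HDR of a pair of count summaries over predictive draws.

    ``summary='totals'`` pairs (total road kills, total hunter kills); any
    other value must be a pair of years ``(y_road, y_hunt)`` pairing the
    two channels' counts in those years.
    """
    if len(draws) < 100:
        raise ValueError("need at least 100 draws for an empirical HDR")
    if not (0.0 < level <= 1.0):
        raise ValueError("level must lie in (0, 1]")
    if summary == "totals":
        x = np.array([s.road_counts.sum() for s in draws])
        y = np.array([s.hunter_counts.sum() for s in draws])
    else:
        yr_road, yr_hunt = summary
        x = np.array(
            [s.road_counts[yr_road - s.first_year] for s in draws]
        )
        y = np.array(
            [s.hunter_counts[yr_hunt - s.first_year] for s in draws]
        )
    x_edges = np.arange(-0.5, x.max() + 1.5)
    y_edges = np.arange(-0.5, y.max() + 1.5)
    hist, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    dens = ndimage.gaussian_filter(hist, smooth_sigma)
    dens /= dens.sum()
    order = np.argsort(dens.ravel())[::-1]
    cum = np.cumsum(dens.ravel()[order])
    k = int(np.searchsorted(cum, level)) + 1
    mask = np.zeros(dens.size, dtype=bool)
    mask[order[:k]] = True
    return HDRRegion(
        level=level,
        x_edges=x_edges,
        y_edges=y_edges,
        member_mask=mask.reshape(dens.shape),
    )
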