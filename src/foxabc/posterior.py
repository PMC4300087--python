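"""Posterior summaries of accepted populations and forward projection.

Summaries mirror the headline inference quantities: the probability the
population is extinct at the end of the observation window, the
distribution of the number of occupied cells (marginal and conditional on
being extant), the year-of-introduction table, the net-reproduction-rate
exceedance P(NRR > 1), the dispersal-mode shares, and a per-cell occupancy
probability map.  Projection continues each accepted run forward from its
stored end-of-window state under its own parameters to estimate the time
to the next carcass discovery or extinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Landscape
from .priors import T0_MAX, T0_MIN, Priors, net_reproduction_rate
from .simulate import simulate_trajectory
from .smc import ParticlePopulation


def _weighted_quantile(
    values: np.ndarray, weights: np.ndarray, qs
) -> np.ndarray:
    """Quantiles of a weighted sample (inverse weighted empirical CDF)."""
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cum = np.cumsum(w) / w.sum()
    return np.array([v[np.searchsorted(cum, q, side="left")] for q in np.atleast_1d(qs)])


@dataclass
class PosteriorSummary:
    """Weighted summaries of a particle population (or prior ensemble)."""

    end_year: int
    p_extinct: float
    intro_year_table: dict[int, float]
    occupied_counts: np.ndarray
    weights: np.ndarray
    #: conditional on extant: median and one-sided upper 95% occupied cells
    occupied_median_extant: float | None
    occupied_upper95_extant: float | None
    occupied_ci_extant: tuple[float, float] | None
    p_nrr_gt_1: float
    p_nrr_gt_1_extant: float | None
    kernel_shares: dict[str, float]
    nrr: np.ndarray
    marginals: dict[str, np.ndarray]

    def occupancy_class_probs(self) -> dict[str, float]:
        """Mass in the extinct / 1-5 / 6-10 / >10 occupied-cell classes."""
        n, w = self.occupied_counts, self.weights
        return {
            "extinct": float(w[n == 0].sum()),
            "1-5": float(w[(n >= 1) & (n <= 5)].sum()),
            "6-10": float(w[(n >= 6) & (n <= 10)].sum()),
            ">10": float(w[n > 10].sum()),
        }


def summarize_population(
    pop: ParticlePopulation, end_year: int = 2013
) -> PosteriorSummary:
    """Weighted posterior summaries as of the end of ``end_year``."""
    if len(pop) == 0:
        raise ValueError("population is empty")
    if len(pop.trajectories) != len(pop):
        raise ValueError("population has no attached trajectories")
    w = pop.weights
    occ = np.array(
        [traj.occupied_at(end_year).size for traj in pop.trajectories]
    )
    extinct = occ == 0
    p_ext = float(w[extinct].sum())

    years = np.arange(T0_MIN, T0_MAX + 1)
    t0s = np.array([t.t0 for t in pop.particles])
    intro_table = {
        int(y): float(w[t0s == y].sum()) for y in years
    }

    nrr = np.array(
        [net_reproduction_rate(t.lam, t.q) for t in pop.particles]
    )
    p_nrr = float(w[nrr > 1.0].sum())

    extant = ~extinct
    if extant.any():
        we = w[extant] / w[extant].sum()
        med, hi95 = _weighted_quantile(occ[extant], we, [0.5, 0.95])
        lo, hi = _weighted_quantile(occ[extant], we, [0.025, 0.975])
        p_nrr_ext = float(we[nrr[extant] > 1.0].sum())
        cond = (float(med), float(hi95), (float(lo), float(hi)), p_nrr_ext)
    else:
        cond = (None, None, None, None)

    kernels = np.array([t.kernel for t in pop.particles])
    shares = {k: float(w[kernels == k].sum()) for k in ("natural", "invasion")}

    marginals = {
        name: np.array([getattr(t, name) for t in pop.particles])
        for name in ("q", "lam", "p_road", "p_hunt")
    }
    return PosteriorSummary(
        end_year=end_year,
        p_extinct=p_ext,
        intro_year_table=intro_table,
        occupied_counts=occ,
        weights=w.copy(),
        occupied_median_extant=cond[0],
        occupied_upper95_extant=cond[1],
        occupied_ci_extant=cond[2],
        p_nrr_gt_1=p_nrr,
        p_nrr_gt_1_extant=cond[3],
        kernel_shares=shares,
        nrr=nrr,
        marginals=marginals,
    )


def occupancy_probability_map(
    pop: ParticlePopulation, landscape: Landscape, end_year: int = 2013
) -> np.ndarray:
    """Per-cell weighted probability of occupancy at the end of ``end_year``."""
    prob = np.zeros(landscape.n_rows * landscape.n_cols)
    for w, traj in zip(pop.weights, pop.trajectories):
        cells = traj.occupied_at(end_year)
        if cells.size:
            prob[cells] += w
    return prob.reshape(landscape.n_rows, landscape.n_cols)


@dataclass
class ProjectionSummary:
    """Cumulative outcome probabilities for the years after the window."""

    years: np.ndarray
    p_extinct: np.ndarray
    p_detect: np.ndarray           # >=1 new road OR hunter kill
    p_detect_road_only: np.ndarray
    p_extinct_or_detect: np.ndarray
    n_reps: int

    def validate(self) -> None:
        for curve in (
            self.p_extinct, self.p_detect, self.p_detect_road_only,
            self.p_extinct_or_detect,
        ):
            if np.any(np.diff(curve) < -1e-12):
                raise AssertionError("cumulative curve must be nondecreasing")
            if np.any((curve < -1e-12) | (curve > 1 + 1e-12)):
                raise AssertionError("probabilities must lie in [0, 1]")
        if np.any(
            self.p_extinct_or_detect
            < np.maximum(self.p_extinct, self.p_detect) - 1e-12
        ):
            raise AssertionError(
                "either-outcome curve must dominate both components"
            )


def project_population(
    pop: ParticlePopulation,
    landscape: Landscape,
    horizon_year: int = 2023,
    n_reps: int = 30,
    rng: np.random.Generator | None = None,
    start_year: int = 2013,
) -> ProjectionSummary:
    """Project every accepted run forward under its own parameters.

    Each particle's stored end-of-window occupancy is continued for
    ``n_reps`` stochastic replicates (fresh hunting layer per replicate);
    particles already extinct contribute extinction from the first
    projected year.  Curves are weighted averages over particles and
    replicates.
    """
    if horizon_year <= start_year:
        raise ValueError("horizon_year must exceed start_year")
    rng = rng if rng is not None else np.random.default_rng()
    years = np.arange(start_year + 1, horizon_year + 1)
    ny = years.size
    p_ext = np.zeros(ny)
    p_det = np.zeros(ny)
    p_det_road = np.zeros(ny)
    p_either = np.zeros(ny)
    for w, theta, traj in zip(pop.weights, pop.particles, pop.trajectories):
        state = traj.occupied_at(start_year)
        if state.size == 0:
            p_ext += w
            p_either += w
            continue
        for _ in range(n_reps):
            fut = simulate_trajectory(
                theta,
                landscape,
                horizon_year,
                rng,
                initial=state,
                start_year=start_year + 1,
                record_occupancy=False,
                record_events=False,
            )
            wr = w / n_reps
            ext = np.zeros(ny, dtype=bool)
            if fut.extinct_year is not None:
                ext[years >= fut.extinct_year] = True
            det = np.cumsum(fut.road_counts + fut.hunter_counts) > 0
            det_road = np.cumsum(fut.road_counts) > 0
            p_ext += wr * ext
            p_det += wr * det
            p_det_road += wr * det_road
            p_either += wr * (ext | det)
    out = ProjectionSummary(
        years=years,
        p_extinct=p_ext,
        p_detect=p_det,
        p_detect_road_only=p_det_road,
        p_extinct_or_detect=p_either,
        n_reps=n_reps,
    )
    out.validate()
    return out


def implicit_prior_summary(
    priors: Priors,
    landscape: Landscape,
    n_sims: int,
    rng: np.random.Generator,
    end_year: int = 2013,
) -> PosteriorSummary:
    """Prior-implied summary: forward-simulate prior draws, no conditioning.

    The derived-quantity distribution this induces (extinction probability,
    occupied-cell counts at the end of the window, ...) is the "implicit
    prior" against which the posterior is contrasted.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    particles = []
    trajectories = []
    for _ in range(n_sims):
        theta = priors.sample(rng)
        traj = simulate_trajectory(
            theta, landscape, end_year, rng,
            record_occupancy=False, record_events=False,
        )
        particles.append(theta)
        trajectories.append(traj)
    pop = ParticlePopulation(
        particles=particles,
        weights=np.full(n_sims, 1.0 / n_sims),
        trajectories=trajectories,
        generation=0,
        tolerances=(np.inf, np.inf),
    )
    return summarize_population(pop, end_year=end_year)
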