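"""ABC rejection and ABC-SMC samplers for the invasion model.

The rejection sampler draws parameters from the prior, simulates a carcass
dataset, and accepts when the per-channel L1 discrepancies fall within
tolerance.  The SMC sampler is a particle filter in the style of Toni et
al.: a population of weighted particles is pushed through a decreasing
road-kill tolerance schedule (default 2, 1, 0; the hunter-kill tolerance is
0 throughout), each generation resampling from the previous one, jittering
with truncated-Normal perturbation kernels, and reweighting by
pi(theta) / sum_j w_j K(theta | theta_j).

Because the discrepancy is additive over years, a simulation is aborted as
soon as its already-incurred discrepancy exceeds the tolerance; this early
rejection is exact (it never changes an accept/reject outcome) and is what
makes the zero-tolerance generation tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .landscape import Landscape
from .observation import CarcassSeries, discrepancy, extract_carcass_series
from .priors import (
    CONTINUOUS_FIELDS,
    KERNELS,
    Priors,
    Theta,
    theta_to_vector,
    vector_to_theta,
)
from .simulate import Trajectory, simulate_trajectory

_BOUNDS = np.array(list(CONTINUOUS_FIELDS.values()))  # (8, 2)
_LO, _HI = _BOUNDS[:, 0], _BOUNDS[:, 1]


class ABCError(RuntimeError):
    """Sampling failed; carries the partial population for resumption."""

    def __init__(self, message: str, partial=None, diagnostics=None):
        super().__init__(message)
        self.partial = partial
        self.diagnostics = diagnostics or {}


@dataclass
class ABCConfig:
    """Settings of the ABC samplers."""

    n_particles: int = 1000
    road_tolerance_schedule: tuple[int, ...] = (2, 1, 0)
    hunt_tolerance: int = 0
    #: perturbation bandwidth = bandwidth_factor x weighted s.d. per parameter
    bandwidth_factor: float = np.sqrt(2.0)
    kernel_flip_probability: float = 0.1
    #: attempt budget per generation
    max_attempts: int = 10**6
    end_year: int = 2013

    def validate(self) -> None:
        """The headline analysis uses schedule (2, 1, 0) ending at an exact
        match; scaled-down studies may stop at a looser final tolerance."""
        sched = self.road_tolerance_schedule
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if len(sched) == 0 or any(
            b > a for a, b in zip(sched, sched[1:])
        ):
            raise ValueError("tolerance schedule must be nonincreasing")


@dataclass
class ParticlePopulation:
    """Weighted particles with their accepted trajectories."""

    particles: list[Theta]
    weights: np.ndarray
    trajectories: list[Trajectory]
    generation: int
    tolerances: tuple[float, float]
    acceptance_rate: float = np.nan
    bandwidths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        total = self.weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must sum to a positive finite value")
        self.weights = self.weights / total

    def __len__(self) -> int:
        return len(self.particles)

    def vectors(self) -> np.ndarray:
        """(n, 8) continuous coordinates of every particle."""
        return np.array([theta_to_vector(t) for t in self.particles])

    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def resample_index(self, rng: np.random.Generator) -> int:
        return int(rng.choice(len(self.particles), p=self.weights))

    def to_frame(self):
        import pandas as pd

        rows = []
        for theta, w in zip(self.particles, self.weights):
            rows.append(
                {
                    "t0": theta.t0,
                    "setback0": theta.setbacks[0],
                    "setback1": theta.setbacks[1],
                    "setback2": theta.setbacks[2],
                    "kernel": theta.kernel,
                    "q": theta.q,
                    "lam": theta.lam,
                    "p_road": theta.p_road,
                    "p_hunt": theta.p_hunt,
                    "weight": w,
                    "generation": self.generation,
                }
            )
        return pd.DataFrame(rows)


def simulate_and_test(
    theta: Theta,
    landscape: Landscape,
    observed: CarcassSeries,
    eps_road: float,
    eps_hunt: float,
    rng: np.random.Generator,
    record: bool = True,
) -> tuple[bool, Trajectory | None]:
    """Simulate one dataset and test it against the tolerances.

    The comparison window runs from the particle's introduction year to the
    end of the observed window.  The simulation is aborted (exactly) once
    the running discrepancy can no longer come back under tolerance.
    """
    end_year = observed.last_year
    obs = observed.restrict(theta.t0, end_year)
    obs_road = {int(y): int(c) for y, c in zip(obs.years, obs.road_counts)}
    obs_hunt = {int(y): int(c) for y, c in zip(obs.years, obs.hunter_counts)}
    running = {"road": 0, "hunt": 0}

    def callback(year: int, n_road: int, n_hunt: int) -> bool:
        running["road"] += abs(obs_road[year] - n_road)
        running["hunt"] += abs(obs_hunt[year] - n_hunt)
        return running["road"] > eps_road or running["hunt"] > eps_hunt

    traj = simulate_trajectory(
        theta,
        landscape,
        end_year,
        rng,
        record_occupancy=record,
        record_events=record,
        year_callback=callback,
    )
    if traj.aborted:
        return False, None
    sim = extract_carcass_series(traj, theta.t0, end_year)
    d_road, d_hunt = discrepancy(obs, sim)
    if d_road <= eps_road and d_hunt <= eps_hunt:
        return True, traj
    return False, None


def abc_rejection(
    observed: CarcassSeries,
    priors: Priors,
    landscape: Landscape,
    config: ABCConfig,
    rng: np.random.Generator,
    tolerances: tuple[float, float] | None = None,
) -> ParticlePopulation:
    """Plain rejection ABC at a fixed tolerance pair (defaults to the
    final entry of the schedule and the hunter tolerance)."""
    config.validate()
    eps_road = (
        tolerances[0] if tolerances else config.road_tolerance_schedule[-1]
    )
    eps_hunt = tolerances[1] if tolerances else config.hunt_tolerance
    particles: list[Theta] = []
    trajectories: list[Trajectory] = []
    attempts = 0
    while len(particles) < config.n_particles:
        if attempts >= config.max_attempts:
            raise ABCError(
                f"attempt budget exhausted: {len(particles)}/"
                f"{config.n_particles} particles after {attempts} attempts",
                partial=(particles, trajectories),
                diagnostics={"eps": (eps_road, eps_hunt)},
            )
        attempts += 1
        theta = priors.sample(rng)
        ok, traj = simulate_and_test(
            theta, landscape, observed, eps_road, eps_hunt, rng
        )
        if ok:
            particles.append(theta)
            trajectories.append(traj)
    return ParticlePopulation(
        particles=particles,
        weights=np.full(len(particles), 1.0 / len(particles)),
        trajectories=trajectories,
        generation=1,
        tolerances=(eps_road, eps_hunt),
        acceptance_rate=len(particles) / attempts,
    )


def compute_bandwidths(pop: ParticlePopulation, factor: float) -> np.ndarray:
    """factor x weighted standard deviation of each continuous coordinate,
    floored to a small fraction of the support width so kernel densities
    stay proper even if a coordinate has collapsed."""
    vecs = pop.vectors()
    mean = pop.weights @ vecs
    var = pop.weights @ (vecs - mean) ** 2
    bw = factor * np.sqrt(var)
    return np.maximum(bw, 1e-6 * (_HI - _LO))


def perturb_particle(
    theta: Theta,
    bandwidths: np.ndarray,
    priors: Priors,
    rng: np.random.Generator,
    flip_probability: float = 0.1,
    max_tries: int = 10_000,
) -> Theta:
    """Jitter a particle with Normal noise, redrawing until in support.

    Continuous coordinates (three setbacks, q, lam, p_road, p_hunt and the
    latent introduction year) each get independent Normal noise; the latent
    year is floored to an integer; the dispersal-mode indicator flips with
    a small probability.  The redraw-until-valid rule makes the effective
    kernel a product of truncated Normals (used by :func:`smc_weight`).
    """
    vec = theta_to_vector(theta)
    bandwidths = np.asarray(bandwidths, dtype=float)
    for _ in range(max_tries):
        prop = vec + bandwidths * rng.standard_normal(vec.size)
        # open bounds for the Beta-supported probabilities
        if np.all(prop >= _LO) and np.all(prop < _HI) and prop[5] > 0 \
                and prop[6] > 0:
            break
    else:
        raise ABCError("perturbation failed to land in support")
    kernel = theta.kernel
    if flip_probability > 0 and rng.random() < flip_probability:
        kernel = KERNELS[1 - KERNELS.index(kernel)]
    return vector_to_theta(prop, kernel)


def _kernel_logdensity(
    new_vec: np.ndarray,
    new_kernel: str,
    prev_vecs: np.ndarray,
    prev_kernels: np.ndarray,
    bandwidths: np.ndarray,
    flip_probability: float,
) -> np.ndarray:
    """log K(theta_new | theta_j) for every previous particle j.

    Continuous coordinates: truncated-Normal densities on their supports.
    Latent year: probability mass of the floored year's unit interval under
    the truncated Normal.  Kernel indicator: flip/stay probability.
    """
    h = np.asarray(bandwidths, dtype=float)
    mu = prev_vecs  # (n, 8)
    # per-coordinate truncation normalizer
    z = norm.cdf((_HI - mu) / h) - norm.cdf((_LO - mu) / h)
    z = np.maximum(z, 1e-300)
    # continuous coordinates 0..6
    x = new_vec[:7]
    logpdf = (
        norm.logpdf((x - mu[:, :7]) / h[:7]) - np.log(h[:7])
    ) - np.log(z[:, :7])
    out = logpdf.sum(axis=1)
    # latent year: mass of [floor(t), floor(t)+1)
    t = np.floor(new_vec[7])
    mass = norm.cdf((t + 1 - mu[:, 7]) / h[7]) - norm.cdf((t - mu[:, 7]) / h[7])
    out += np.log(np.maximum(mass, 1e-300)) - np.log(z[:, 7])
    if flip_probability > 0:
        flip = prev_kernels != new_kernel
        out += np.where(
            flip, np.log(flip_probability), np.log1p(-flip_probability)
        )
    else:
        out += np.where(prev_kernels != new_kernel, -np.inf, 0.0)
    return out


def smc_weight(
    theta_new: Theta,
    previous: ParticlePopulation,
    bandwidths: np.ndarray,
    priors: Priors,
    flip_probability: float = 0.1,
    _prev_vecs: np.ndarray | None = None,
    _prev_kernels: np.ndarray | None = None,
) -> float:
    """Unnormalized Toni et al. weight pi(theta) / sum_j w_j K(theta|theta_j)."""
    lp = priors.logpdf(theta_new)
    if lp == -np.inf:
        return 0.0
    vecs = previous.vectors() if _prev_vecs is None else _prev_vecs
    kernels = (
        np.array([t.kernel for t in previous.particles])
        if _prev_kernels is None
        else _prev_kernels
    )
    logk = _kernel_logdensity(
        theta_to_vector(theta_new),
        theta_new.kernel,
        vecs,
        kernels,
        bandwidths,
        flip_probability,
    )
    m = logk.max()
    denom = np.sum(previous.weights * np.exp(logk - m))
    if denom <= 0 or not np.isfinite(denom):
        raise ABCError("SMC weight denominator collapsed (bandwidths too small)")
    return float(np.exp(lp - m - np.log(denom)))


def abc_smc(
    observed: CarcassSeries,
    priors: Priors,
    landscape: Landscape,
    config: ABCConfig,
    rng: np.random.Generator,
    progress: bool = False,
) -> ParticlePopulation:
    """ABC sequential Monte Carlo through the road-tolerance schedule.

    Generation 1 is rejection sampling from the prior at the first
    tolerance; each later generation resamples the previous population by
    weight, perturbs, simulates, accepts under the next tolerance, and is
    reweighted with :func:`smc_weight`.  At the final (zero) tolerance every
    accepted trajectory reproduces the observed carcass record exactly in
    number and timing.
    """
    config.validate()
    sched = config.road_tolerance_schedule
    pop = abc_rejection(
        observed, priors, landscape, config, rng,
        tolerances=(sched[0], config.hunt_tolerance),
    )
    if progress:
        print(
            f"generation 1 (eps_road={sched[0]}): "
            f"acceptance {pop.acceptance_rate:.4f}"
        )
    for g, eps_road in enumerate(sched[1:], start=2):
        bw = compute_bandwidths(pop, config.bandwidth_factor)
        prev_vecs = pop.vectors()
        prev_kernels = np.array([t.kernel for t in pop.particles])
        particles: list[Theta] = []
        trajectories: list[Trajectory] = []
        weights: list[float] = []
        attempts = 0
        while len(particles) < config.n_particles:
            if attempts >= config.max_attempts:
                raise ABCError(
                    f"generation {g}: attempt budget exhausted with "
                    f"{len(particles)}/{config.n_particles} particles",
                    partial=pop,
                    diagnostics={"generation": g, "eps_road": eps_road},
                )
            attempts += 1
            j = rng.choice(len(pop), p=pop.weights)
            theta = perturb_particle(
                pop.particles[j], bw, priors, rng,
                config.kernel_flip_probability,
            )
            ok, traj = simulate_and_test(
                theta, landscape, observed, eps_road, config.hunt_tolerance,
                rng,
            )
            if ok:
                particles.append(theta)
                trajectories.append(traj)
                weights.append(
                    smc_weight(
                        theta, pop, bw, priors,
                        config.kernel_flip_probability,
                        _prev_vecs=prev_vecs, _prev_kernels=prev_kernels,
                    )
                )
        pop = ParticlePopulation(
            particles=particles,
            weights=np.array(weights),
            trajectories=trajectories,
            generation=g,
            tolerances=(eps_road, config.hunt_tolerance),
            acceptance_rate=len(particles) / attempts,
            bandwidths=bw,
        )
        if progress:
            print(
                f"generation {g} (eps_road={eps_road}): "
                f"acceptance {pop.acceptance_rate:.4f}, "
                f"ESS {pop.effective_sample_size():.0f}"
            )
    return pop
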