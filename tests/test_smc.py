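import numpy as np
import pytest
from scipy import stats

import foxabc
from foxabc.priors import theta_to_vector
from foxabc.smc import (
    ABCConfig,
    ABCError,
    ParticlePopulation,
    abc_rejection,
    abc_smc,
    compute_bandwidths,
    perturb_particle,
    smc_weight,
)

from conftest import MINI_TRUTH


def _weighted_ks(x1, w1, x2, w2):
    """Two-sample KS statistic between weighted empirical CDFs."""
    grid = np.sort(np.concatenate([x1, x2]))
    o1, o2 = np.argsort(x1), np.argsort(x2)
    c1 = np.cumsum(w1[o1]) / w1.sum()
    c2 = np.cumsum(w2[o2]) / w2.sum()
    F1 = c1[np.clip(np.searchsorted(x1[o1], grid, side="right") - 1, 0, None)]
    F2 = c2[np.clip(np.searchsorted(x2[o2], grid, side="right") - 1, 0, None)]
    return np.max(np.abs(F1 - F2))


class TestRejection:
    def test_infinite_tolerance_recovers_prior(self, mini_landscape, priors,
                                               mini_observed):
        cfg = ABCConfig(n_particles=800, max_attempts=10_000)
        rng = np.random.default_rng(1)
        pop = abc_rejection(
            mini_observed, priors, mini_landscape, cfg, rng,
            tolerances=(np.inf, np.inf),
        )
        assert pop.acceptance_rate == 1.0
        np.testing.assert_allclose(pop.weights, 1 / 800)
        q = np.array([t.q for t in pop.particles])
        lam = np.array([t.lam for t in pop.particles])
        p_road = np.array([t.p_road for t in pop.particles])
        assert stats.kstest(q, stats.uniform(0, 1).cdf).pvalue > 0.001
        assert stats.kstest(lam, stats.uniform(0, 2).cdf).pvalue > 0.001
        assert stats.kstest(p_road, stats.beta(10, 90).cdf).pvalue > 0.001

    def test_accepted_particles_meet_tolerance(self, mini_landscape, priors,
                                               mini_observed):
        cfg = ABCConfig(n_particles=40, max_attempts=200_000)
        rng = np.random.default_rng(2)
        pop = abc_rejection(
            mini_observed, priors, mini_landscape, cfg, rng,
            tolerances=(2, 3),
        )
        for theta, traj in zip(pop.particles, pop.trajectories):
            sim = foxabc.extract_carcass_series(traj, theta.t0, 2005)
            obs = mini_observed.restrict(theta.t0, 2005)
            d_road, d_hunt = foxabc.discrepancy(obs, sim)
            assert d_road <= 2 and d_hunt <= 3

    def test_budget_exhaustion_raises_with_partial(self, mini_landscape,
                                                   priors, mini_observed):
        cfg = ABCConfig(n_particles=1000, max_attempts=50)
        with pytest.raises(ABCError, match="budget"):
            abc_rejection(
                mini_observed, priors, mini_landscape, cfg,
                np.random.default_rng(3), tolerances=(0, 0),
            )


class TestPerturbation:
    def test_zero_bandwidth_zero_flip_is_identity(self, priors):
        theta = priors.sample(np.random.default_rng(0))
        out = perturb_particle(
            theta, np.zeros(8), priors, np.random.default_rng(1),
            flip_probability=0.0,
        )
        assert out == theta

    def test_boundary_thetas_stay_in_support(self, priors):
        rng = np.random.default_rng(2)
        near_edge = foxabc.Theta(
            t0=2001, setbacks=(0.01, 24.99, 0.01), kernel="natural",
            q=0.999, lam=0.001, p_road=0.002, p_hunt=0.998,
        )
        bw = np.full(8, 0.5)
        for _ in range(2000):
            out = perturb_particle(near_edge, bw, priors, rng)
            assert out.in_support()

    def test_interior_mean_preserved(self, priors):
        rng = np.random.default_rng(3)
        theta = foxabc.Theta(
            t0=1998, setbacks=(12.0, 12.0, 12.0), kernel="invasion",
            q=0.5, lam=1.0, p_road=0.10, p_hunt=0.10,
        )
        bw = np.full(8, 0.02)
        qs = [perturb_particle(theta, bw, priors, rng).q for _ in range(10_000)]
        se = 0.02 / np.sqrt(10_000)
        assert np.mean(qs) == pytest.approx(0.5, abs=3 * se + 1e-4)

    def test_kernel_flips_at_configured_rate(self, priors):
        rng = np.random.default_rng(4)
        theta = priors.sample(rng)
        flips = sum(
            perturb_particle(theta, np.full(8, 0.1), priors, rng,
                             flip_probability=0.1).kernel != theta.kernel
            for _ in range(10_000)
        )
        assert flips / 10_000 == pytest.approx(0.1, abs=0.01)


class TestSMCWeight:
    def _two_particle_pop(self):
        thetas = [
            foxabc.Theta(1997, (5.0, 10.0, 15.0), "natural", 0.4, 0.8, 0.10, 0.09),
            foxabc.Theta(2000, (2.0, 20.0, 7.0), "invasion", 0.7, 1.2, 0.12, 0.11),
        ]
        trajs = [None, None]
        return ParticlePopulation(
            particles=thetas, weights=np.array([0.3, 0.7]),
            trajectories=trajs, generation=1, tolerances=(2, 0),
        )

    def test_matches_hand_computed_value(self, priors):
        # independent re-derivation of pi(theta)/sum_j w_j K(theta|theta_j)
        # with truncated-Normal kernels, written directly from the formula
        pop = self._two_particle_pop()
        bw = np.array([1.0, 1.0, 1.0, 0.05, 0.1, 0.01, 0.01, 0.8])
        new = foxabc.Theta(1998, (6.0, 12.0, 14.0), "natural", 0.45, 0.9, 0.11, 0.10)
        got = smc_weight(new, pop, bw, priors, flip_probability=0.1)

        from foxabc.priors import CONTINUOUS_FIELDS

        bounds = np.array(list(CONTINUOUS_FIELDS.values()))
        x = theta_to_vector(new)
        denom = 0.0
        for w, th in zip(pop.weights, pop.particles):
            mu = theta_to_vector(th)
            k = 1.0
            for i in range(8):
                lo, hi = bounds[i]
                z = stats.norm.cdf((hi - mu[i]) / bw[i]) - stats.norm.cdf(
                    (lo - mu[i]) / bw[i]
                )
                if i == 7:  # latent year: mass of the unit interval
                    t = np.floor(x[7])
                    num = stats.norm.cdf((t + 1 - mu[i]) / bw[i]) - stats.norm.cdf(
                        (t - mu[i]) / bw[i]
                    )
                    k *= num / z
                else:
                    k *= stats.norm.pdf(x[i], mu[i], bw[i]) / z
            k *= 0.1 if th.kernel != new.kernel else 0.9
            denom += w * k
        expect = np.exp(priors.logpdf(new)) / denom
        assert got == pytest.approx(expect, rel=1e-9)

    def test_outside_support_weight_zero(self, priors):
        pop = self._two_particle_pop()
        bad = foxabc.Theta(1998, (6.0, 12.0, 14.0), "natural", 1.2, 0.9, 0.11, 0.10)
        assert smc_weight(bad, pop, np.full(8, 0.1), priors) == 0.0


class TestSMC:
    def test_single_loose_generation_equals_rejection_from_prior(
        self, mini_landscape, priors, mini_observed
    ):
        cfg = ABCConfig(
            n_particles=50, road_tolerance_schedule=(np.inf,),
            hunt_tolerance=np.inf, max_attempts=1000,
        )
        pop = abc_smc(
            mini_observed, priors, mini_landscape, cfg,
            np.random.default_rng(5),
        )
        assert pop.generation == 1
        assert pop.acceptance_rate == 1.0
        np.testing.assert_allclose(pop.weights, 1 / 50)

    def test_smc_matches_rejection_on_miniature_problem(
        self, mini_landscape, priors, mini_observed
    ):
        """SMC and plain rejection at the same final tolerance should give
        very similar approximate posteriors (preregistered per-marginal KS
        threshold 0.15 at 400 particles)."""
        final = (2, 3)
        cfg_r = ABCConfig(n_particles=400, max_attempts=10**6,
                          hunt_tolerance=3)
        rej = abc_rejection(
            mini_observed, priors, mini_landscape, cfg_r,
            np.random.default_rng(6), tolerances=final,
        )
        cfg_s = ABCConfig(
            n_particles=400, road_tolerance_schedule=(4, 2),
            hunt_tolerance=3, max_attempts=10**6,
        )
        # schedule ends at eps_road=2 = the rejection tolerance
        smc = abc_smc(
            mini_observed, priors, mini_landscape, cfg_s,
            np.random.default_rng(7),
        )
        assert smc.tolerances == (2, 3)
        for field in ("q", "lam", "p_road", "p_hunt"):
            xr = np.array([getattr(t, field) for t in rej.particles])
            xs = np.array([getattr(t, field) for t in smc.particles])
            ks = _weighted_ks(xr, rej.weights, xs, smc.weights)
            assert ks < 0.15, f"{field}: KS={ks:.3f}"
        # population invariants
        assert np.all(smc.weights >= 0)
        assert smc.weights.sum() == pytest.approx(1.0)
        assert all(t.in_support() for t in smc.particles)
        # tolerance monotonicity: final acceptances valid at earlier eps
        for theta, traj in zip(smc.particles, smc.trajectories):
            sim = foxabc.extract_carcass_series(traj, theta.t0, 2005)
            obs = mini_observed.restrict(theta.t0, 2005)
            d_road, d_hunt = foxabc.discrepancy(obs, sim)
            assert d_road <= 4 and d_hunt <= 3

    def test_parameter_recovery_coverage(self, mini_landscape, priors):
        """Refitting data simulated from a known theta*: 95% posterior
        intervals should cover the true q, lam, p_road in >=80% of refits
        (ABC tolerance slack acknowledged).  Each refit picks its
        tolerances as 5% pilot quantiles of the prior discrepancy
        distribution, the standard self-scaling rule that keeps dense and
        sparse datasets equally affordable."""
        covered = {"q": 0, "lam": 0, "p_road": 0}
        n_fits = 20
        for i in range(n_fits):
            series, _ = foxabc.generate_dataset(
                MINI_TRUTH, mini_landscape, 2005, seed=1000 + i
            )
            n = 2005 - 1995 + 1
            road = np.zeros(n, int)
            hunt = np.zeros(n, int)
            road[series.first_year - 1995:] = series.road_counts
            hunt[series.first_year - 1995:] = series.hunter_counts
            obs = foxabc.CarcassSeries(1995, 2005, road, hunt)
            rng = np.random.default_rng(2000 + i)
            d_road, d_hunt = [], []
            for _ in range(1500):
                th = priors.sample(rng)
                traj = foxabc.simulate_trajectory(
                    th, mini_landscape, 2005, rng,
                    record_occupancy=False, record_events=False,
                )
                sim = foxabc.extract_carcass_series(traj, th.t0, 2005)
                a, b = foxabc.discrepancy(obs.restrict(th.t0, 2005), sim)
                d_road.append(a)
                d_hunt.append(b)
            eps = (
                max(1, int(np.quantile(d_road, 0.05))),
                max(1, int(np.quantile(d_hunt, 0.05))),
            )
            cfg = ABCConfig(n_particles=60, max_attempts=300_000)
            pop = abc_rejection(
                obs, priors, mini_landscape, cfg, rng, tolerances=eps
            )
            for field in covered:
                x = np.array([getattr(t, field) for t in pop.particles])
                lo, hi = np.percentile(x, [2.5, 97.5])
                if lo <= getattr(MINI_TRUTH, field) <= hi:
                    covered[field] += 1
        for field, n_cov in covered.items():
            assert n_cov >= 0.8 * n_fits, f"{field} covered {n_cov}/{n_fits}"

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError, match="nonincreasing"):
            ABCConfig(road_tolerance_schedule=(1, 2, 0)).validate()
        with pytest.raises(ValueError):
            ABCConfig(n_particles=0).validate()


def test_bandwidths_positive_and_scale_with_spread(mini_prior_population):
    bw = compute_bandwidths(mini_prior_population, np.sqrt(2))
    assert np.all(bw > 0)
    vecs = mini_prior_population.vectors()
    sd = vecs.std(axis=0)
    np.testing.assert_allclose(bw, np.sqrt(2) * sd, rtol=0.05)
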