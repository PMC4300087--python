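# Methods

`foxabc` infers the status of an invasive red-fox population from a sparse
record of carcass discoveries. It combines a stochastic spatial invasion
simulator with an observation model for road kills and hunter kills, and fits
the joint model to the dated carcass record by Approximate Bayesian
Computation (ABC). This note documents the model, its assumptions, the
numerical choices, and what the synthetic test bed does and does not show.

## The invasion model

The world is a grid of 5 km x 5 km cells (roughly one fox home range), each
either suitable or unsuitable habitat. The population state in year *t* is
the set of occupied cells; a cell is occupied when it holds at least one
breeding fox unit. Within-cell abundance is not modelled.

The introduction happens in a single year `t0` (discrete-uniform prior on
1995-2001): one founding cell per release region, three regions in all. Each
founding cell is drawn uniformly from the suitable cells of its 30 km release
disc whose distance to the nearest major road matches that region's setback
parameter (continuous Uniform(0, 25) km prior, independent across regions,
matched to cells within +-2.5 km — half a cell width — with a
nearest-distance fallback where a bin is empty).

Each subsequent year applies, in order:

1. **Survival.** Every occupied cell independently remains occupied with
   probability `q` (Uniform(0, 1) prior). Survival is applied before
   reproduction, so a cell's expected lifetime output of daughter cells is
   the geometric series

   NRR = lam*q + lam*q^2 + ... = lam*q / (1 - q),

   the net reproduction rate. NRR > 1 is necessary, not sufficient, for
   establishment.

2. **Observation.** A surviving cell traversed by a major road produces a
   road-kill carcass with probability `p_road`; independently, a surviving
   cell subject to hunting produces a hunter-kill carcass with probability
   `p_hunt` (at most one of each per cell-year). Kills never change
   occupancy — a road kill is demographically trivial for the cell. Hunting
   effort is spatially uneven: at the start of every simulation replicate
   each cell is independently flagged as hunted with probability 0.5.
   Both observation probabilities carry Beta(10, 90) priors (mean 10%).
   The road-kill prior is anchored by the Phillip Island control record:
   35 road kills over 25 years on an island of about four occupied cells
   gives a rate of 0.35 per cell-year, i.e. a yearly probability of at least
   one road kill of 1 - exp(-0.35) ~ 0.30, treated as an upper bound.

3. **Reproduction.** Every surviving cell spawns Poisson(`lam`) propagules
   (`lam` ~ Uniform(0, 2)). Each propagule is displaced by the dispersal
   kernel; it founds a new occupied cell only if it lands on a suitable,
   unoccupied, in-grid cell different from its source. Failed propagules are
   lost. Two kernels, with a 50/50 prior on the mode indicator:

   * *natural* — displacement distance follows a Weibull truncated at 30 km
     whose parameters are solved numerically so that P(D <= 2 km) = 0.70 and
     E[D | D > 2] = 11 km (juvenile-dispersal field summaries); direction
     uniform. The solution (shape 0.146461, scale 357514.9 km) is unique up
     to the truncation, verified from multiple starting points, and frozen
     as module constants with a test that re-solves it. Most natural
     propagules land inside their source cell and are lost — short-range
     recaptures represent cubs that never left the natal range.
   * *invasion* — the target cell is uniform over all cells within 30 km of
     the source (flat circular kernel), excluding the source.

   Grid boundaries are absorbing.

## Observed data and discrepancy

The observed record (packaged as a CSV fixture) is: one hunter kill in 2001;
road kills in 2003, 2005 and 2006; nothing else through 2013. The 2005 entry
is the Lillico Beach carcass, assigned to 2005 (first sighted December 2005)
rather than its official February-2006 report date.

The ABC discrepancy between observed and simulated records is the L1
distance between yearly count vectors, computed separately for the road and
hunter channels, over the window from the particle's own introduction year
to 2013. Carcass locations are deliberately not used. Because the
discrepancy is additive over years, the simulator aborts a run as soon as
the already-incurred discrepancy exceeds the tolerance (and, once extinct,
adds the remaining observed counts); this early rejection never changes an
accept/reject decision and is what makes the zero-tolerance generation
affordable.

## Samplers

*Rejection*: draw from the prior, simulate, accept when both channel
discrepancies fall within tolerance.

*SMC*: a particle filter over the road-kill tolerance schedule 2 -> 1 -> 0
with the hunter tolerance 0 throughout. Generation 1 is rejection at the
first tolerance. Later generations resample the previous population by
weight (multinomial), perturb, simulate, and reweight with the standard
particle-filter correction pi(theta) / sum_j w_j K(theta | theta_j).
Implementation policy where the procedure is underdetermined:

* Perturbation kernels are independent Normals per continuous coordinate
  (the three setbacks, q, lam, p_road, p_hunt, and the introduction year on
  a continuous latent scale floored to an integer). Proposals outside the
  prior support are redrawn, so the effective kernel is a product of
  truncated Normals; `K` in the weight uses the truncation-normalized
  densities, and the latent-year component uses the probability mass of the
  floored year's unit interval.
* Bandwidths are sqrt(2) times the weighted standard deviation of each
  coordinate in the previous generation, floored at 1e-6 of the support
  width.
* The kernel-mode indicator flips with probability 0.1 per perturbation.
* At the final tolerance every accepted trajectory reproduces the observed
  record exactly in number and timing.

A fit's acceptance rates, tolerances and bandwidths are recorded on the
returned population. Budget exhaustion raises an error carrying the partial
population.

## Posterior summaries, projection, sensitivity, predictive checks

Summaries are weighted over particles: P(extinct at end 2013), the
introduction-year table, occupied-cell distributions (marginal and
conditional on extant, with weighted median and one-sided upper 95% bound),
P(NRR > 1), kernel-mode shares, and a per-cell occupancy probability map.

Projection continues each accepted run from its stored end-2013 occupancy
under its own parameters (default 30 replicates per particle, fresh hunting
layer per replicate) out to a configurable horizon (default 2023), giving
cumulative curves for extinction, for detection of at least one new carcass
(an any-channel curve and a road-only variant, since either convention is
defensible), and for the either-or event. The curves are checked on every
run to be nondecreasing and to dominate their components.

Prior sensitivity uses importance reweighting: with modified prior pi',
weights are multiplied by pi'(theta)/pi(theta) and renormalized, reported
with the effective sample size (ESS), and a warning when the ESS falls below
a floor. The +-10% observation-prior shifts keep the Beta concentration at
a+b = 100, so a +10% mean shift of Beta(10, 90) is Beta(11, 89).

Predictive draws sample parameters from the prior or the weighted
population and re-run the simulator with fresh randomness; draws are
summarized by pairwise count statistics with empirical highest-density
regions (a smoothed 2-D histogram, cells ranked by density until the target
mass is covered).

## Synthetic test bed

The packaged reference landscape is generated deterministically from a fixed
seed: a noisy-ellipse island holding exactly 1256 suitable cells (48% of
land, biased toward the north-east with the south-west left unsuitable, as
on the real island), two sparse major-road transects, and three release
regions placed so every setback bin 0-25 km has candidate cells. It emulates
the aggregate geometry of the real landscape — cell counts, suitability
fraction, road sparsity, release-region support — but not the coastline,
the true road topology, or the fragmentation pattern of real land use.
Posterior and prior-implied quantities that depend on fine spatial structure
therefore carry landscape approximation error in addition to Monte Carlo
error, which is why headline comparisons are made at loose, pre-stated
bands.

Recovery experiments use a miniature problem (30x30 grid, 150 suitable
cells, one road, window ending 2005) with strongly observable true
parameters, where tolerances of 1-2 carcasses retain meaningful acceptance
rates.

## Reproduction-state convention

One structural ambiguity deserves explicit note. This package implements
reproduction by the *survivors* of the year, which is what the stated event
ordering and the NRR geometric series (first term lam*q) imply; the
simulator's mean lifetime offspring demonstrably converges to
lam*q/(1 - q). An alternative convention — drawing reproduction from the
year-*start* occupancy, so that cells reproduce in the year they die and
newborns are safe in their birth year — implies NRR = lam/(1 - q) and
produces materially lower prior extinction probabilities and larger prior
populations. Prior-implied quantities (extinction probability near 39% and
typical extant populations of a few hundred cells have been reported for
models of this family) are reachable only under that alternative
convention; under the convention implemented here the prior extinction
probability is necessarily above ~0.6. The package keeps the
survivors-reproduce convention because it is the one the model's own NRR
formula encodes.

## Problem sizes and numerical choices

* Implicit-prior ensembles use 10^4 simulations (the acceptance script's
  size; Monte Carlo s.e. on the extinction probability ~0.5%).
* The in-suite SMC demonstration uses a deliberately small particle count;
  at the exact-match tolerance the per-particle cost is dominated by the
  ~10^-4..10^-5 probability that even a well-placed parameter vector
  regenerates the record exactly, so full-size fits (hundreds to a
  thousand particles) are multi-hour to multi-day single-CPU runs, run via
  `examples/04_fit_smc.py` with a larger `n_particles`.
* Weighted quantiles use the inverse weighted empirical CDF.
* Degenerate inputs: a landscape with no roads is rejected at generation
  (the setback prior requires road support); an all-unsuitable raster is
  rejected at load; zero-bandwidth perturbation coordinates are floored;
  an all-extinct population reports conditional summaries as undefined
  rather than NaN.

## Known limitations

* Within-cell abundance, sex structure, den behaviour, bait-induced
  mortality and traffic-volume-dependent road hazard are all folded into
  q, p_road, p_hunt.
* The hunting layer is a spatially uncorrelated 50% Bernoulli field;
  real hunting effort is clustered.
* The discrepancy ignores carcass locations, as in the source analysis.
* Importance reweighting cannot explore priors far from the fitted one
  (ESS collapse is reported, not repaired).
* The synthetic landscape reproduces aggregate geometry only; conclusions
  about the real incursion require the real habitat and road rasters, which
  can be supplied through `load_landscape`.
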