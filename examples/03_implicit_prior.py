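"""The implicit prior: push the parameter priors through the simulator.

Forward-simulating prior draws with no data conditioning shows what the
prior assumptions alone imply about extinction and population size at the
end of 2013 — the baseline against which the posterior is contrasted.
(The acceptance script runs this at 10^4 draws; 2000 here for speed.)
"""

import numpy as np

import foxabc

landscape = foxabc.make_reference_landscape()
priors = foxabc.Priors()
summary = foxabc.implicit_prior_summary(
    priors, landscape, n_sims=2000, rng=np.random.default_rng(1)
)
print(f"implicit prior P(extinct by end 2013) = {summary.p_extinct:.1%}")
if summary.occupied_median_extant is not None:
    lo, hi = summary.occupied_ci_extant
    print(f"occupied cells | extant: median {summary.occupied_median_extant:.0f}, "
          f"95% interval ({lo:.0f}, {hi:.0f})")
print(f"P(NRR > 1) = {summary.p_nrr_gt_1:.1%}")
# A large share of prior mass is demographically weak (NRR < 1), so the
# prior already considers extinction a substantial possibility before any
# carcass data are seen.
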