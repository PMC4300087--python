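"""Simulate one invasion trajectory from chosen parameters.

Each year every occupied cell survives with probability q, surviving
road/hunted cells may produce carcasses (p_road, p_hunt), and survivors
spawn Poisson(lam) propagules through the dispersal kernel.  NRR =
lam*q/(1-q) summarizes demographic vigour: values above 1 are necessary
for establishment.
"""

import numpy as np

import foxabc

landscape = foxabc.make_reference_landscape()
theta = foxabc.Theta(
    t0=1999,
    setbacks=(5.0, 12.0, 2.0),
    kernel="natural",
    q=0.85,
    lam=0.9,
    p_road=0.12,
    p_hunt=0.10,
)
print("NRR =", round(foxabc.net_reproduction_rate(theta.lam, theta.q), 2))

rng = np.random.default_rng(4)
traj = foxabc.simulate_trajectory(theta, landscape, 2013, rng)
for year, n, r, h in zip(
    traj.years, traj.n_occupied, traj.road_counts, traj.hunter_counts
):
    marks = "R" * r + "H" * h
    print(f"  {year}: {n:4d} occupied cells {marks}")
if traj.extinct:
    print(f"population went extinct in {traj.extinct_year}")
else:
    print(f"population extant at end 2013 with "
          f"{traj.occupied_at(2013).size} occupied cells")
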