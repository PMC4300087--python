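"""Yearly stochastic invasion dynamics on the cell grid.

State is the set of occupied cells (a cell = one breeding fox unit).
Within each year the event order is: survival (probability q per occupied
cell), observation (a surviving road cell yields a road kill with
probability p_road; independently a surviving hunted cell yields a hunter
kill with probability p_hunt; kills do not change occupancy), then
reproduction (each survivor spawns Poisson(lam) propagules through the
dispersal kernel; a propagule landing off-grid, on unsuitable ground, on
its source cell or on an already-occupied cell is lost).

Hunting effort is uneven: at the start of every simulation replicate each
cell is independently flagged as hunted with probability 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dispersal import invasion_kernel_offsets, sample_natural_dispersal_distance
from .landscape import Landscape, candidate_release_cells
from .priors import Theta

HUNTING_PROBABILITY = 0.5


@dataclass
class HuntingLayer:
    """Per-cell flag: is the cell subject to hunter observation this run?"""

    hunted: np.ndarray  # (n_rows, n_cols) bool


def assign_hunting_layer(
    landscape: Landscape,
    rng: np.random.Generator,
    probability: float = HUNTING_PROBABILITY,
) -> HuntingLayer:
    """Independently flag each cell as hunted (redrawn every replicate)."""
    return HuntingLayer(
        hunted=rng.random((landscape.n_rows, landscape.n_cols)) < probability
    )


@dataclass
class Trajectory:
    """One realisation of the invasion plus its carcass events.

    ``occupied`` maps year -> sorted flat cell indices; if the run was
    simulated with ``record_occupancy=False`` only the final year is kept.
    ``road_kill_cells`` / ``hunter_kill_cells`` map year -> cells that
    produced a kill (present when ``record_events=True``); the per-year
    counts are always available.
    """

    t0: int
    end_year: int
    years: np.ndarray
    n_occupied: np.ndarray
    road_counts: np.ndarray
    hunter_counts: np.ndarray
    occupied: dict[int, np.ndarray] = field(default_factory=dict)
    road_kill_cells: dict[int, np.ndarray] = field(default_factory=dict)
    hunter_kill_cells: dict[int, np.ndarray] = field(default_factory=dict)
    extinct_year: int | None = None
    aborted: bool = False

    def occupied_at(self, year: int) -> np.ndarray:
        if self.extinct_year is not None and year >= self.extinct_year:
            return np.empty(0, dtype=np.int64)
        if year in self.occupied:
            return self.occupied[year]
        raise KeyError(f"occupancy for year {year} was not recorded")

    @property
    def extinct(self) -> bool:
        return self.extinct_year is not None


def trajectory_to_frame(trajectory: Trajectory, landscape: Landscape):
    """Long-format event table: (year, cell_row, cell_col, event_type).

    ``event_type`` is one of occupied / road_kill / hunter_kill; occupancy
    rows are emitted for every recorded year.
    """
    import pandas as pd

    rows = []
    for year, cells in sorted(trajectory.occupied.items()):
        r, c = np.divmod(cells, landscape.n_cols)
        rows += [
            {"year": year, "cell_row": int(i), "cell_col": int(j),
             "event_type": "occupied"}
            for i, j in zip(r, c)
        ]
    for label, events in (
        ("road_kill", trajectory.road_kill_cells),
        ("hunter_kill", trajectory.hunter_kill_cells),
    ):
        for year, cells in sorted(events.items()):
            r, c = np.divmod(cells, landscape.n_cols)
            rows += [
                {"year": year, "cell_row": int(i), "cell_col": int(j),
                 "event_type": label}
                for i, j in zip(r, c)
            ]
    return pd.DataFrame(rows, columns=["year", "cell_row", "cell_col",
                                       "event_type"])


def initialize_occupancy(
    theta: Theta, landscape: Landscape, rng: np.random.Generator
) -> np.ndarray:
    """Founding occupied cells: one per release site at its setback."""
    if len(landscape.release_sites) != 3:
        raise ValueError("landscape must define exactly 3 release sites")
    cells = []
    for site, setback in zip(landscape.release_sites, theta.setbacks):
        cand = candidate_release_cells(landscape, site, setback)
        cells.append(int(cand[rng.integers(cand.size)]))
    return np.unique(np.array(cells, dtype=np.int64))


def disperse_propagule(
    source: int,
    kernel: str,
    landscape: Landscape,
    rng: np.random.Generator,
    occupied: np.ndarray | None = None,
) -> int | None:
    """Single-propagule convenience wrapper around the vectorised kernel."""
    occ = np.zeros(landscape.n_rows * landscape.n_cols, dtype=bool)
    if occupied is not None:
        occ[occupied] = True
    targets = _disperse_many(
        np.array([source], dtype=np.int64), kernel, landscape, occ, rng
    )
    return int(targets[0]) if targets.size else None


def _disperse_many(
    sources: np.ndarray,
    kernel: str,
    landscape: Landscape,
    occ_flat: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Targets of a batch of propagules; lost propagules are dropped."""
    if sources.size == 0:
        return sources
    nr, nc = landscape.n_rows, landscape.n_cols
    sr, sc = np.divmod(sources, nc)
    if kernel == "natural":
        d = sample_natural_dispersal_distance(rng, sources.size)
        ang = rng.uniform(0.0, 2.0 * np.pi, sources.size)
        cs = landscape.cell_size
        ty = (sr + 0.5) * cs + d * np.sin(ang)
        tx = (sc + 0.5) * cs + d * np.cos(ang)
        tr = np.floor(ty / cs).astype(np.int64)
        tc = np.floor(tx / cs).astype(np.int64)
    elif kernel == "invasion":
        offs = _offsets_cache(landscape.cell_size)
        pick = offs[rng.integers(offs.shape[0], size=sources.size)]
        tr, tc = sr + pick[:, 0], sc + pick[:, 1]
    else:
        raise ValueError(f"unknown dispersal kernel {kernel!r}")
    ok = (tr >= 0) & (tr < nr) & (tc >= 0) & (tc < nc)
    tr, tc = tr[ok], tc[ok]
    t = tr * nc + tc
    t = t[landscape.suitable.ravel()[t] & ~occ_flat[t] & (t != sources[ok])]
    return np.unique(t)


_OFFSETS: dict[float, np.ndarray] = {}


def _offsets_cache(cell_size: float) -> np.ndarray:
    if cell_size not in _OFFSETS:
        _OFFSETS[cell_size] = invasion_kernel_offsets(cell_size)
    return _OFFSETS[cell_size]


def step_year(
    occupied: np.ndarray,
    theta: Theta,
    landscape: Landscape,
    hunting: HuntingLayer,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One year of dynamics: survival, observation, reproduction.

    Returns (new occupied cells, road-kill cells, hunter-kill cells).
    """
    occupied = np.asarray(occupied, dtype=np.int64)
    survivors = occupied[rng.random(occupied.size) < theta.q]

    road_flat = landscape.road.ravel()
    on_road = survivors[road_flat[survivors]]
    road_kills = on_road[rng.random(on_road.size) < theta.p_road]
    in_hunt = survivors[hunting.hunted.ravel()[survivors]]
    hunter_kills = in_hunt[rng.random(in_hunt.size) < theta.p_hunt]

    n_prop = rng.poisson(theta.lam, survivors.size)
    sources = np.repeat(survivors, n_prop)
    occ_flat = np.zeros(landscape.n_rows * landscape.n_cols, dtype=bool)
    occ_flat[survivors] = True
    colonists = _disperse_many(sources, theta.kernel, landscape, occ_flat, rng)
    # colonists are unique and disjoint from survivors by construction
    new_occupied = np.concatenate([survivors, colonists])
    return new_occupied, road_kills, hunter_kills


def simulate_trajectory(
    theta: Theta,
    landscape: Landscape,
    end_year: int,
    rng: np.random.Generator,
    hunting: HuntingLayer | None = None,
    initial: np.ndarray | None = None,
    start_year: int | None = None,
    record_occupancy: bool = True,
    record_events: bool = True,
    year_callback=None,
) -> Trajectory:
    """Run the invasion from the introduction year through ``end_year``.

    A fresh hunting layer is drawn unless one is supplied (projection of an
    accepted run continues under new layers).  ``initial``/``start_year``
    override the default founding event, letting a stored end-of-window
    state be projected forward.  ``year_callback(year, n_road, n_hunt)``
    is invoked after every simulated year; a truthy return aborts the run
    (used by the ABC samplers for exact early rejection).
    """
    start = theta.t0 if start_year is None else start_year
    if end_year < start:
        raise ValueError("end_year precedes the start of the simulation")
    if hunting is None:
        hunting = assign_hunting_layer(landscape, rng)
    occupied = (
        initialize_occupancy(theta, landscape, rng)
        if initial is None
        else np.asarray(initial, dtype=np.int64)
    )
    years = np.arange(start, end_year + 1)
    n_years = years.size
    traj = Trajectory(
        t0=theta.t0,
        end_year=end_year,
        years=years,
        n_occupied=np.zeros(n_years, dtype=np.int64),
        road_counts=np.zeros(n_years, dtype=np.int64),
        hunter_counts=np.zeros(n_years, dtype=np.int64),
    )
    for i, year in enumerate(years):
        occupied, road_kills, hunter_kills = step_year(
            occupied, theta, landscape, hunting, rng
        )
        traj.n_occupied[i] = occupied.size
        traj.road_counts[i] = road_kills.size
        traj.hunter_counts[i] = hunter_kills.size
        if record_occupancy:
            traj.occupied[int(year)] = occupied
        if record_events:
            if road_kills.size:
                traj.road_kill_cells[int(year)] = road_kills
            if hunter_kills.size:
                traj.hunter_kill_cells[int(year)] = hunter_kills
        if occupied.size == 0:
            traj.extinct_year = int(year)
            break
        if year_callback is not None and year_callback(
            int(year), int(road_kills.size), int(hunter_kills.size)
        ):
            traj.aborted = True
            break
    if not record_occupancy and traj.extinct_year is None and not traj.aborted:
        traj.occupied[end_year] = occupied
    return traj
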