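"""Grid-cell landscape: habitat mask, road network, release regions.

The world is a rectangular grid of 5 km x 5 km cells (row 0 = north,
0-based indices).  A cell is either suitable fox habitat or not, and is
either traversed by a major road or not.  Distances are Euclidean between
cell centroids, in km.  Release regions are discs of configurable radius
(default 30 km) around named township cells; the introduction prior places
founding cells inside a region at a given setback distance from the
nearest major road.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

CELL_KM = 5.0
#: half a cell width; tolerance for matching a continuous setback to cells
SETBACK_BIN_KM = CELL_KM / 2.0


class LandscapeError(ValueError):
    """Raised when a landscape violates an invariant or cannot be built."""


@dataclass(frozen=True)
class ReleaseSite:
    """A named release region: disc of ``radius_km`` around a center cell."""

    name: str
    row: int
    col: int
    radius_km: float = 30.0


@dataclass
class Landscape:
    """The cell-grid world on which invasion and observation run.

    Attributes
    ----------
    suitable : (n_rows, n_cols) bool array
        True where a breeding fox unit can occupy the cell.
    road : (n_rows, n_cols) bool array
        True where a major road traverses the cell.
    dist_road : (n_rows, n_cols) float array
        Euclidean centroid distance (km) to the nearest road cell
        (``inf`` everywhere if there are no road cells).
    release_sites : list of ReleaseSite
    """

    suitable: np.ndarray
    road: np.ndarray
    dist_road: np.ndarray
    release_sites: list[ReleaseSite] = field(default_factory=list)
    cell_size: float = CELL_KM

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)
        self.road = np.asarray(self.road, dtype=bool)
        if self.suitable.shape != self.road.shape:
            raise LandscapeError(
                f"suitability {self.suitable.shape} and road {self.road.shape} "
                "layers have mismatched shapes"
            )
        if self.cell_size <= 0:
            raise LandscapeError("cell_size must be positive")
        if not self.suitable.any():
            raise LandscapeError("landscape has no suitable cells")

    @property
    def n_rows(self) -> int:
        return self.suitable.shape[0]

    @property
    def n_cols(self) -> int:
        return self.suitable.shape[1]

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())

    # flat-index helpers used throughout the simulator
    def flat(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return rows * self.n_cols + cols

    def unflat(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.divmod(idx, self.n_cols)

    def centroid_km(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) centroid coordinates in km, y increasing southwards."""
        return (
            (np.asarray(rows) + 0.5) * self.cell_size,
            (np.asarray(cols) + 0.5) * self.cell_size,
        )


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic Tasmania-like landscape generator."""

    target_suitable_cells: int = 1256
    suitable_fraction: float = 0.48
    n_rows: int = 72
    n_cols: int = 54
    n_roads: int = 2
    road_jitter_km: float = 10.0
    release_radius_km: float = 30.0
    release_site_names: tuple[str, ...] = ("longford", "oatlands", "sthelens")
    #: minimum spacing between release-site centers, km
    release_spacing_km: float = 55.0

    def validate(self) -> None:
        if not (0.0 < self.suitable_fraction <= 1.0):
            raise LandscapeError("suitable_fraction must lie in (0, 1]")
        if self.target_suitable_cells < 1:
            raise LandscapeError("target_suitable_cells must be >= 1")
        if self.n_rows * self.n_cols < self.target_suitable_cells:
            raise LandscapeError("grid too small for target_suitable_cells")
        if self.n_roads < 1:
            raise LandscapeError(
                "road-support error: the setback prior requires at least one "
                "major road (n_roads >= 1)"
            )


def compute_distance_to_road(landscape: Landscape) -> np.ndarray:
    """Per-cell Euclidean centroid distance (km) to the nearest road cell.

    Exact (uses the Euclidean distance transform); every road cell maps to 0.
    With no road cells the field is all-infinite and a warning is emitted.
    """
    road = landscape.road
    if not road.any():
        import warnings

        warnings.warn("landscape has no road cells; dist_road is infinite")
        return np.full(road.shape, np.inf)
    return ndimage.distance_transform_edt(~road, sampling=landscape.cell_size)


def _site_candidates(
    landscape: Landscape, site: ReleaseSite
) -> tuple[np.ndarray, np.ndarray]:
    """Suitable in-radius cells of a site with their road distances,
    sorted by distance (cached on the landscape for sampler throughput)."""
    cache = getattr(landscape, "_site_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(landscape, "_site_cache", cache)
    key = (site.name, site.row, site.col, site.radius_km)
    if key not in cache:
        rows, cols = np.nonzero(landscape.suitable)
        cy, cx = landscape.centroid_km(rows, cols)
        sy, sx = landscape.centroid_km(site.row, site.col)
        in_radius = np.hypot(cy - sy, cx - sx) <= site.radius_km
        if not in_radius.any():
            raise LandscapeError(
                f"release site {site.name!r} has no suitable cell within "
                f"{site.radius_km} km"
            )
        rows, cols = rows[in_radius], cols[in_radius]
        d = landscape.dist_road[rows, cols]
        order = np.argsort(d, kind="stable")
        cache[key] = (landscape.flat(rows, cols)[order], d[order])
    return cache[key]


def candidate_release_cells(
    landscape: Landscape, site: ReleaseSite, setback: float
) -> np.ndarray:
    """Suitable cells of a release region matching a road setback.

    Returns flat indices of suitable cells within ``site.radius_km`` of the
    site center whose ``dist_road`` lies within +/- half a cell width
    (2.5 km) of ``setback``.  If that bin is empty the suitable in-radius
    cells whose ``dist_road`` is nearest to ``setback`` are returned, so the
    setback prior always has support wherever the region has suitable cells.
    """
    if not (0.0 <= setback <= 25.0):
        raise ValueError(f"setback {setback} outside [0, 25] km")
    cells, d = _site_candidates(landscape, site)
    lo = np.searchsorted(d, setback - SETBACK_BIN_KM, side="left")
    hi = np.searchsorted(d, setback + SETBACK_BIN_KM, side="right")
    if hi > lo:
        return cells[lo:hi]
    gap = np.abs(d - setback)
    return cells[gap <= gap.min() + 1e-9]  # nearest-distance fallback


def _rasterize_polyline(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Cells crossed by a piecewise-linear transect given as (row, col) floats."""
    mask = np.zeros(shape, dtype=bool)
    for a, b in zip(points[:-1], points[1:]):
        n = int(np.ceil(np.hypot(*(b - a)) * 4)) + 2
        t = np.linspace(0.0, 1.0, n)
        rr = np.clip(np.round(a[0] + t * (b[0] - a[0])).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(a[1] + t * (b[1] - a[1])).astype(int), 0, shape[1] - 1)
        mask[rr, cc] = True
    return mask


def _island_and_suitability(config: LandscapeConfig, rng: np.random.Generator):
    """Land mask (noisy ellipse) and a suitability score favouring the NE."""
    nr, nc = config.n_rows, config.n_cols
    n_land = int(round(config.target_suitable_cells / config.suitable_fraction))
    rows, cols = np.mgrid[0:nr, 0:nc]
    # ellipse semi-axes sized so the island holds ~n_land cells
    aspect = nr / nc
    b = np.sqrt(n_land / (np.pi * aspect))
    a = aspect * b
    u = (rows - (nr - 1) / 2) / a
    v = (cols - (nc - 1) / 2) / b
    boundary_noise = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), 4.0)
    score = u**2 + v**2 + 0.25 * boundary_noise
    land = score <= np.partition(score.ravel(), n_land - 1)[n_land - 1]

    # suitability: smooth noise plus a NE gradient (SW left as unsuitable
    # conservation estate, as on the real island)
    noise = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), 3.0)
    noise /= noise.std()
    grad = -0.9 * rows / nr + 0.9 * cols / nc
    suit_score = np.where(land, grad + 0.8 * noise, -np.inf)
    k = config.target_suitable_cells
    thresh = np.partition(suit_score.ravel(), -k)[-k]
    suitable = suit_score >= thresh
    # ties at the threshold could overshoot; trim deterministically
    if suitable.sum() > k:
        extra = suitable.sum() - k
        rr, cc = np.nonzero(suitable & (suit_score == thresh))
        suitable[rr[:extra], cc[:extra]] = False
    return land, suitable


def _make_roads(
    config: LandscapeConfig, suitable: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sparse piecewise-linear major roads crossing the suitable region."""
    nr, nc = suitable.shape
    rows, cols = np.nonzero(suitable)
    r_lo, r_hi = rows.min(), rows.max()
    c_lo, c_hi = cols.min(), cols.max()
    j = config.road_jitter_km / CELL_KM
    mask = np.zeros((nr, nc), dtype=bool)
    # road 1: northern highway, west->east across the top of the suitable area
    r_top = r_lo + 0.18 * (r_hi - r_lo)
    pts = np.array(
        [
            [r_top + rng.uniform(-j, j), c_lo + 1],
            [r_top + rng.uniform(-j, j), (c_lo + c_hi) / 2],
            [r_top + rng.uniform(-j, j), c_hi - 1],
        ]
    )
    mask |= _rasterize_polyline(pts, (nr, nc))
    if config.n_roads >= 2:
        # road 2: midlands spine, north->south through the center-east
        c_mid = c_lo + 0.55 * (c_hi - c_lo)
        pts = np.array(
            [
                [r_top, c_mid + rng.uniform(-j, j)],
                [(r_lo + r_hi) / 2, c_mid + rng.uniform(-j, j)],
                [r_hi - 2, c_mid + rng.uniform(-j, j)],
            ]
        )
        mask |= _rasterize_polyline(pts, (nr, nc))
    return mask


_SETBACK_PROBE = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)


def _site_supports_all_setbacks(
    landscape: Landscape, site: ReleaseSite
) -> bool:
    try:
        return all(
            candidate_release_cells(landscape, site, s).size > 0
            and np.all(
                np.abs(
                    landscape.dist_road.ravel()[
                        candidate_release_cells(landscape, site, s)
                    ]
                    - s
                )
                <= SETBACK_BIN_KM
            )
            for s in _SETBACK_PROBE
        )
    except LandscapeError:
        return False


def _place_release_sites(
    landscape: Landscape, config: LandscapeConfig
) -> list[ReleaseSite]:
    """Greedy search for well-spread centers supporting every setback bin."""
    rows, cols = np.nonzero(landscape.suitable)
    order = np.argsort(landscape.dist_road[rows, cols])  # start near roads
    chosen: list[ReleaseSite] = []
    names = iter(config.release_site_names)
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if chosen:
            dy = (np.array([s.row for s in chosen]) - r) * CELL_KM
            dx = (np.array([s.col for s in chosen]) - c) * CELL_KM
            if np.hypot(dy, dx).min() < config.release_spacing_km:
                continue
        cand = ReleaseSite(next(names, f"site{len(chosen)}"), r, c,
                           config.release_radius_km)
        if _site_supports_all_setbacks(landscape, cand):
            chosen.append(cand)
        if len(chosen) == 3:
            return chosen
    raise LandscapeError(
        "unsatisfiable config: could not place 3 release sites with suitable "
        "cells at every setback bin 0-25 km; the road network does not leave "
        "road-free pockets within the release radius"
    )


def generate_synthetic_landscape(
    config: LandscapeConfig | None = None, seed: int = 0
) -> Landscape:
    """Generate a Tasmania-like synthetic landscape.

    A noisy-ellipse island is populated with exactly
    ``config.target_suitable_cells`` suitable cells (~48% of land, biased to
    the north-east), crossed by sparse major roads, with three release
    regions each guaranteed to contain suitable cells at every road-setback
    bin from 0 to 25 km.  Deterministic given ``seed``.
    """
    config = config or LandscapeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    land, suitable = _island_and_suitability(config, rng)
    road = _make_roads(config, suitable, rng) & land
    if not road.any():
        raise LandscapeError(
            "road-support error: generated road network is empty; the "
            "introduction prior requires roads"
        )
    ls = Landscape(suitable=suitable, road=road,
                   dist_road=np.empty_like(suitable, dtype=float))
    ls.dist_road = compute_distance_to_road(ls)
    ls.release_sites = _place_release_sites(ls, config)
    return ls


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grids + JSON sidecar + release-site CSV


def _write_asc(path: Path, grid: np.ndarray, cell_size: float) -> None:
    nr, nc = grid.shape
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.astype(int), fmt="%d")


def _read_asc(path: Path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise LandscapeError(f"{path}: grid does not match declared shape")
    return grid, header["cellsize"]


def save_landscape(landscape: Landscape, directory: str | Path) -> None:
    """Write suitability/road .asc grids, sites.csv and meta.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_asc(d / "suitable.asc", landscape.suitable, landscape.cell_size)
    _write_asc(d / "road.asc", landscape.road, landscape.cell_size)
    pd.DataFrame(
        [
            {"name": s.name, "row": s.row, "col": s.col, "radius_km": s.radius_km}
            for s in landscape.release_sites
        ]
    ).to_csv(d / "sites.csv", index=False)
    (d / "meta.json").write_text(
        json.dumps({"cell_size": landscape.cell_size, "row0": "north"}, indent=1)
    )


def load_landscape(directory: str | Path) -> Landscape:
    """Load a landscape saved by :func:`save_landscape` (round-trip exact)."""
    d = Path(directory)
    suitable, cs1 = _read_asc(d / "suitable.asc")
    road, cs2 = _read_asc(d / "road.asc")
    if suitable.shape != road.shape:
        raise LandscapeError(
            f"shape mismatch: suitability {suitable.shape} vs road {road.shape}"
        )
    if cs1 != cs2:
        raise LandscapeError("cell sizes of suitability and road layers differ")
    meta = json.loads((d / "meta.json").read_text())
    sites = [
        ReleaseSite(str(r.name), int(r.row), int(r.col), float(r.radius_km))
        for r in pd.read_csv(d / "sites.csv").itertuples(index=False)
    ] if (d / "sites.csv").exists() else []
    ls = Landscape(
        suitable=suitable.astype(bool),
        road=road.astype(bool),
        dist_road=np.empty_like(suitable, dtype=float),
        release_sites=sites,
        cell_size=meta["cell_size"],
    )
    ls.dist_road = compute_distance_to_road(ls)
    return ls
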