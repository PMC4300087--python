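"""Carcass-count series, the Tasmanian record, and the ABC discrepancy.

The observable data are yearly counts of fox carcasses discovered through
two channels: road kills (vehicle collisions on major roads) and hunter
kills.  The Tasmanian record comprises four carcasses: one hunter kill in
2001 and road kills in 2003, 2005 and 2006 (the Lillico Beach carcass,
officially reported February 2006, was first sighted in December 2005 and
is assigned to 2005).  The ABC discrepancy between an observed and a
simulated series is the L1 distance on the yearly count vectors, computed
separately per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .simulate import Trajectory

OBS_FIRST_YEAR = 1995
OBS_LAST_YEAR = 2013


@dataclass
class CarcassSeries:
    """Yearly road-kill and hunter-kill counts over a window of years."""

    first_year: int
    last_year: int
    road_counts: np.ndarray
    hunter_counts: np.ndarray

    def __post_init__(self) -> None:
        n = self.last_year - self.first_year + 1
        self.road_counts = np.asarray(self.road_counts, dtype=np.int64)
        self.hunter_counts = np.asarray(self.hunter_counts, dtype=np.int64)
        if self.road_counts.shape != (n,) or self.hunter_counts.shape != (n,):
            raise ValueError("counts must cover every year of the window")
        if (self.road_counts < 0).any() or (self.hunter_counts < 0).any():
            raise ValueError("carcass counts must be nonnegative")

    @property
    def window(self) -> tuple[int, int]:
        return (self.first_year, self.last_year)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def restrict(self, first_year: int, last_year: int) -> "CarcassSeries":
        """Slice to a sub-window (years outside the series are an error)."""
        if first_year < self.first_year or last_year > self.last_year:
            raise ValueError("requested window exceeds the series window")
        i = first_year - self.first_year
        j = last_year - self.first_year + 1
        return CarcassSeries(
            first_year, last_year, self.road_counts[i:j], self.hunter_counts[i:j]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "road_count": self.road_counts,
                "hunter_count": self.hunter_counts,
            }
        )


def observed_tasmanian_data(
    first_year: int = OBS_FIRST_YEAR, last_year: int = OBS_LAST_YEAR
) -> CarcassSeries:
    """The Tasmanian carcass record as a yearly series (zeros elsewhere)."""
    with resources.files("foxabc.data").joinpath(
        "tasmanian_carcasses.csv"
    ).open() as fh:
        records = pd.read_csv(fh)
    n = last_year - first_year + 1
    road = np.zeros(n, dtype=np.int64)
    hunt = np.zeros(n, dtype=np.int64)
    for rec in records.itertuples():
        if not (first_year <= rec.year <= last_year):
            raise ValueError("fixture record outside requested window")
        idx = rec.year - first_year
        if rec.type == "road":
            road[idx] += rec.count
        elif rec.type == "hunter":
            hunt[idx] += rec.count
        else:
            raise ValueError(f"unknown carcass type {rec.type!r}")
    return CarcassSeries(first_year, last_year, road, hunt)


def extract_carcass_series(
    trajectory: Trajectory, first_year: int, last_year: int
) -> CarcassSeries:
    """Yearly kill counts of a trajectory inside a window.

    Years before the introduction (or after an abort/extinction) have zero
    counts; events outside the window are ignored.
    """
    n = last_year - first_year + 1
    road = np.zeros(n, dtype=np.int64)
    hunt = np.zeros(n, dtype=np.int64)
    inside = (trajectory.years >= first_year) & (trajectory.years <= last_year)
    idx = trajectory.years[inside] - first_year
    road[idx] = trajectory.road_counts[inside]
    hunt[idx] = trajectory.hunter_counts[inside]
    return CarcassSeries(first_year, last_year, road, hunt)


def discrepancy(
    observed: CarcassSeries, simulated: CarcassSeries
) -> tuple[int, int]:
    """Per-channel L1 distance between yearly count vectors.

    Both series must share the same window (the ABC comparison window runs
    from the particle's introduction year through the end of observation).
    """
    if observed.window != simulated.window:
        raise ValueError(
            f"window mismatch: observed {observed.window} vs "
            f"simulated {simulated.window}"
        )
    d_road = int(np.abs(observed.road_counts - simulated.road_counts).sum())
    d_hunt = int(np.abs(observed.hunter_counts - simulated.hunter_counts).sum())
    return d_road, d_hunt


def save_series_csv(series: CarcassSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def load_series_csv(path) -> CarcassSeries:
    df = pd.read_csv(path)
    years = df["year"].to_numpy()
    return CarcassSeries(
        int(years.min()),
        int(years.max()),
        df["road_count"].to_numpy(),
        df["hunter_count"].to_numpy(),
    )
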