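"""Gridded outdoor-air exposure.

Outdoor concentrations vary strongly across the country, so the national
attributable fraction is computed over a grid of cells, each carrying a
population (by citizenship) and per-pollutant concentration mean and sd.
Within one Monte Carlo iteration each cell's concentration is drawn from
a normal truncated at zero, the relative risk is evaluated against a
single national background draw (the counterfactual policy level), and
cells are combined by population weight.

Grid files are plain CSV with columns ``cell_id, pop_citizen,
pop_noncitizen, <pollutant>_mean, <pollutant>_sd`` (concentration units
are documented per pollutant in the scenario: ug/m3 for particulates,
ppb for ozone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import ParameterError
from .paf import rr_at

__all__ = ["ExposureGrid", "load_grid", "paf_spatial", "truncated_normal_draws"]

_BASE_COLUMNS = ("cell_id", "pop_citizen", "pop_noncitizen")


@dataclass(frozen=True)
class ExposureGrid:
    """Spatial cells with stratified population and concentration params."""

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.cells
        for col in _BASE_COLUMNS:
            if col not in df.columns:
                raise ParameterError(f"grid is missing column {col!r}")
        if len(df) == 0:
            raise ParameterError("grid has no cells")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ParameterError(f"duplicate cell id {dup!r}")
        if not self.pollutants:
            raise ParameterError("grid defines no <pollutant>_mean/_sd column pairs")
        num = df.drop(columns=["cell_id"])
        if num.isna().any().any():
            col = num.columns[num.isna().any()][0]
            row = df.loc[num[col].isna(), "cell_id"].iloc[0]
            raise ParameterError(f"NaN in column {col!r} at cell {row!r}")
        if (df["pop_citizen"] < 0).any() or (df["pop_noncitizen"] < 0).any():
            raise ParameterError("negative population")
        if self.total_population <= 0:
            raise ParameterError("grid has zero total population")
        for p in self.pollutants:
            bad = df[df[f"{p}_sd"] < 0]
            if len(bad):
                raise ParameterError(
                    f"negative sd for {p!r} at cell {bad['cell_id'].iloc[0]!r}"
                )

    @property
    def pollutants(self) -> tuple:
        cols = set(self.cells.columns)
        return tuple(sorted(
            c[:-5] for c in cols
            if c.endswith("_mean") and f"{c[:-5]}_sd" in cols
        ))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_population(self) -> float:
        return float((self.cells["pop_citizen"] + self.cells["pop_noncitizen"]).sum())

    def population_weights(self) -> np.ndarray:
        pop = (self.cells["pop_citizen"] + self.cells["pop_noncitizen"]).to_numpy(float)
        return pop / pop.sum()

    def concentration_params(self, pollutant: str) -> tuple[np.ndarray, np.ndarray]:
        if pollutant not in self.pollutants:
            raise ParameterError(
                f"pollutant {pollutant!r} not in grid (has {self.pollutants})"
            )
        mean = self.cells[f"{pollutant}_mean"].to_numpy(float)
        sd = self.cells[f"{pollutant}_sd"].to_numpy(float)
        return mean, sd

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def load_grid(path) -> ExposureGrid:
    """Read and validate a grid CSV; errors name the offending cell row."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParameterError(f"grid file {path} is empty") from None
    return ExposureGrid(df)


def truncated_normal_draws(mean: np.ndarray, sd: np.ndarray, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """(n, n_cells) concentration draws from per-cell normals truncated at 0."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = np.empty((n, mean.size), dtype=float)
    fixed = sd == 0
    if fixed.any():
        out[:, fixed] = mean[fixed]
    if (~fixed).any():
        m, s = mean[~fixed], sd[~fixed]
        a = (0.0 - m) / s
        u = rng.random((n, m.size))
        # inverse-CDF on the truncated support keeps draws reproducible
        f0 = stats.norm.cdf(a)
        z = stats.norm.ppf(f0 + u * (1.0 - f0))
        out[:, ~fixed] = np.maximum(m + s * z, 0.0)
    return out


def paf_spatial(grid: ExposureGrid, pollutant: str, rr_draw: float,
                background_draw: float, rng: np.random.Generator,
                unit: float = 10.0, transform: str = "linear",
                n_iterations: int = 1) -> np.ndarray:
    """Population-weighted attributable fraction over grid cells.

    For each iteration, cell concentrations are drawn from per-cell
    truncated normals; one background draw (the counterfactual) is shared
    by all cells; and PAF = 1 - 1 / (population-weighted mean RR), which
    is the categorical formula with one category per cell.  Returns an
    array of length ``n_iterations``.
    """
    w = grid.population_weights()
    mean, sd = grid.concentration_params(pollutant)
    x = truncated_normal_draws(mean, sd, n_iterations, rng)
    rr = rr_at(x, rr_draw, unit=unit, x0=background_draw, transform=transform)
    mean_rr = rr @ w
    return 1.0 - 1.0 / mean_rr
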