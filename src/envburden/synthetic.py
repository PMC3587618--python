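"""Synthetic inputs with known ground truth.

The original study consumed confidential monitor networks, a death
registry and insurance claims.  This module generates stand-ins for each
of those inputs -- a population-weighted concentration grid, stratified
baseline health tables, and whole scenarios whose true attributable
fraction is known analytically -- so every pipeline stage is testable
without any external data.  All generators are deterministic under their
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, ParameterError
from .health import BaselineHealthTable
from .paf import Category, ExposureModel, RelativeRiskModel, RiskPair
from .routes import RouteModel, Scenario
from .spatial import ExposureGrid

__all__ = [
    "SyntheticScenario",
    "generate_grid",
    "generate_grid_multi",
    "generate_known_paf_scenario",
    "generate_baseline_health",
]


def _integerize(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of ``weights * total`` to ints summing to total."""
    raw = weights * total
    base = np.floor(raw).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


def generate_grid(n_cells: int, pop_total: int, conc_mean_range, conc_sd_range,
                  seed: int, pollutant: str = "pm25",
                  citizen_share: float = 0.19,
                  spatial_correlation: float = 0.0) -> ExposureGrid:
    """A synthetic concentration grid with log-uniform population weights.

    Cell populations follow a log-uniform allocation (three decades of
    cell size) normalized to ``pop_total``; per-cell concentration means
    and sds are drawn uniformly from the given ranges.  With
    ``spatial_correlation`` in (0, 1), cell means are smoothed with an
    exponential kernel along the cell index to emulate spatially
    autocorrelated fields (off by default).
    """
    return generate_grid_multi(
        n_cells, pop_total,
        {pollutant: {"mean_range": tuple(conc_mean_range),
                     "sd_range": tuple(conc_sd_range)}},
        seed, citizen_share=citizen_share,
        spatial_correlation=spatial_correlation,
    )


def generate_grid_multi(n_cells: int, pop_total: int, pollutant_ranges: dict,
                        seed: int, citizen_share: float = 0.19,
                        spatial_correlation: float = 0.0) -> ExposureGrid:
    """Multi-pollutant variant of :func:`generate_grid` (shared populations)."""
    if n_cells < 1:
        raise ParameterError(f"n_cells must be >= 1, got {n_cells}")
    if pop_total < 1:
        raise ParameterError(f"pop_total must be >= 1, got {pop_total}")
    if not 0.0 <= citizen_share <= 1.0:
        raise ParameterError("citizen_share outside [0, 1]")
    rng = np.random.default_rng(seed)
    raw = 10.0 ** rng.uniform(0.0, 3.0, n_cells)
    pop = _integerize(raw / raw.sum(), int(pop_total))
    pop_cit = np.round(pop * citizen_share).astype(np.int64)
    data = {
        "cell_id": [f"cell{i:05d}" for i in range(n_cells)],
        "pop_citizen": pop_cit,
        "pop_noncitizen": pop - pop_cit,
    }
    for name, ranges in pollutant_ranges.items():
        lo, hi = ranges["mean_range"]
        slo, shi = ranges["sd_range"]
        if hi < lo or shi < slo or slo < 0:
            raise ParameterError(f"invalid ranges for pollutant {name!r}")
        mean = rng.uniform(lo, hi, n_cells)
        if spatial_correlation > 0 and n_cells > 1:
            # exponential smoothing along the index as a 1-d stand-in for
            # spatial autocorrelation; preserves the marginal range location
            lam = spatial_correlation
            sm = np.copy(mean)
            for i in range(1, n_cells):
                sm[i] = lam * sm[i - 1] + (1 - lam) * mean[i]
            mean = np.clip(sm, lo, hi)
        data[f"{name}_mean"] = mean
        data[f"{name}_sd"] = rng.uniform(slo, shi, n_cells)
    return ExposureGrid(pd.DataFrame(data))


@dataclass(frozen=True)
class SyntheticScenario:
    """A generated scenario with analytically known attribution."""

    seed: int
    structure: str
    pair: RiskPair
    grid: ExposureGrid | None
    truth_paf: float
    truth_count: float

    def scenario(self, grid_name: str = "synthetic") -> Scenario:
        """Wrap the pair as a runnable single-route scenario."""
        grids = {}
        pair = self.pair
        if self.grid is not None:
            grids[grid_name] = {"object": self.grid}
        return Scenario(name=f"synthetic_{self.structure}",
                        routes=(RouteModel(name=pair.route, pairs=(pair,)),),
                        grids=grids)


def generate_known_paf_scenario(target_paf: float, structure: str,
                                seed: int) -> SyntheticScenario:
    """Solve for parameters whose true attributable fraction is ``target_paf``.

    ``categorical`` inverts p(RR-1)/(1+p(RR-1)); ``continuous`` and
    ``spatial`` place all exposure at one concentration x* solving
    rr_unit^(x*/unit) = 1/(1-PAF) above a known counterfactual, so the
    closed form is exact (spatial: homogeneous sd-0 cells).
    """
    if not 0.0 <= target_paf < 1.0:
        raise ParameterError(f"target PAF must lie in [0, 1), got {target_paf}")
    rng = np.random.default_rng(seed)
    baseline = float(rng.integers(1_000, 100_000))
    if structure == "categorical":
        p = float(rng.uniform(0.3, 0.9))
        rr = 1.0 + target_paf / (p * (1.0 - target_paf))
        pair = RiskPair(
            route="indoor_air", pollutant="synthetic", endpoint="synthetic",
            measure="visits", baseline=baseline,
            exposure=ExposureModel(kind="categorical",
                                   categories=(Category("exposed",
                                                        DistributionSpec.point(p)),)),
            rr=RelativeRiskModel(form="categorical",
                                 per_category=(DistributionSpec.point(rr),)),
        )
        grid = None
    elif structure == "continuous":
        rr_unit, unit = 1.06, 10.0
        x_star = unit * math.log(1.0 / (1.0 - target_paf)) / math.log(rr_unit)
        pair = RiskPair(
            route="outdoor_air", pollutant="synthetic", endpoint="synthetic",
            measure="deaths", baseline=baseline,
            exposure=ExposureModel(kind="continuous_scalar",
                                   exposure=DistributionSpec.point(x_star)),
            rr=RelativeRiskModel(form="per_unit_loglinear",
                                 rr_per_unit=DistributionSpec.point(rr_unit),
                                 unit=unit),
        )
        grid = None
    elif structure == "spatial":
        rr_unit, unit, bg = 1.06, 10.0, 20.0
        x_star = bg + unit * math.log(1.0 / (1.0 - target_paf)) / math.log(rr_unit)
        grid = generate_grid(n_cells=25, pop_total=100_000,
                             conc_mean_range=(x_star, x_star),
                             conc_sd_range=(0.0, 0.0), seed=seed,
                             pollutant="synthetic")
        pair = RiskPair(
            route="outdoor_air", pollutant="synthetic", endpoint="synthetic",
            measure="deaths", baseline=baseline,
            exposure=ExposureModel(kind="continuous_spatial",
                                   pollutant="synthetic", grid="synthetic",
                                   background=DistributionSpec.point(bg)),
            rr=RelativeRiskModel(form="per_unit_loglinear",
                                 rr_per_unit=DistributionSpec.point(rr_unit),
                                 unit=unit),
        )
    else:
        raise ParameterError(f"unknown structure {structure!r}")
    return SyntheticScenario(seed=int(seed), structure=structure, pair=pair,
                             grid=grid, truth_paf=float(target_paf),
                             truth_count=float(target_paf) * baseline)


def generate_baseline_health(rates: dict, population: dict, seed: int,
                             noise: bool = False, endpoint: str = "synthetic",
                             measure: str = "deaths") -> BaselineHealthTable:
    """Expected (or binomially sampled) counts per demographic stratum.

    ``rates`` and ``population`` map stratum keys ``(sex, citizenship)``
    to per-person rates and head counts.  With ``noise=False`` (default)
    counts are exactly rate*population, which keeps downstream checks
    sharp; ``noise=True`` draws binomial counts.
    """
    if set(rates) != set(population):
        raise ParameterError("rates and population strata differ")
    rng = np.random.default_rng(seed)
    rows = []
    for key in sorted(rates):
        rate, pop = float(rates[key]), float(population[key])
        if rate < 0:
            raise ParameterError(f"negative rate for stratum {key}")
        if not 0.0 <= rate <= 1.0:
            raise ParameterError(f"rate outside [0, 1] for stratum {key}")
        sex, cit = key
        count = (float(rng.binomial(int(pop), rate)) if noise
                 else rate * pop)
        rows.append(dict(endpoint=endpoint, measure=measure, emirate="synthetic",
                         sex=sex, citizenship=cit, count=count))
    return BaselineHealthTable(pd.DataFrame(rows))
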