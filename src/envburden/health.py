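"""Baseline mortality and health-care-visit tables.

Only one emirate had a complete death registry for the study year, so
national baselines are assembled by computing death rates per
gender-citizenship stratum where the registry is complete and applying
those rates to the population of the remaining emirates.  Morbidity
baselines come from insurance claims covering part of the population for
part of the year, scaled by coverage, period and population factors.

Tables are plain CSV with columns ``endpoint, measure, emirate, sex,
citizenship, age_band, count`` (stratum columns optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import ParameterError

__all__ = ["BaselineHealthTable", "extrapolate_death_rates", "scale_claims"]

_STRATA = ["sex", "citizenship"]


@dataclass(frozen=True)
class BaselineHealthTable:
    """Deaths/visits by endpoint with optional demographic strata."""

    records: pd.DataFrame
    year: int = 2008

    def __post_init__(self) -> None:
        df = self.records
        for col in ("endpoint", "measure", "count"):
            if col not in df.columns:
                raise ParameterError(f"baseline table is missing column {col!r}")
        if (df["count"] < 0).any():
            bad = df.loc[df["count"] < 0].iloc[0]
            raise ParameterError(
                f"negative count for endpoint {bad['endpoint']!r}"
            )
        bad_measure = set(df["measure"]) - {"deaths", "visits"}
        if bad_measure:
            raise ParameterError(f"unknown measure(s) {sorted(bad_measure)}")

    def total(self, endpoint: str, measure: str) -> float:
        df = self.records
        sel = df[(df["endpoint"] == endpoint) & (df["measure"] == measure)]
        if len(sel) == 0:
            raise ParameterError(f"no rows for endpoint {endpoint!r} ({measure})")
        return float(sel["count"].sum())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, year: int = 2008) -> "BaselineHealthTable":
        return cls(pd.read_csv(path), year=year)


def _check_strata(name: str, df: pd.DataFrame) -> pd.DataFrame:
    for col in _STRATA:
        if col not in df.columns:
            raise ParameterError(f"{name} table is missing stratum column {col!r}")
    if df.duplicated(_STRATA).any():
        raise ParameterError(f"{name} table has duplicate strata")
    return df.set_index(_STRATA)


def extrapolate_death_rates(abu_dhabi_deaths: pd.DataFrame,
                            abu_dhabi_pop: pd.DataFrame,
                            other_pop: pd.DataFrame,
                            endpoint: str = "all_causes") -> BaselineHealthTable:
    """National deaths from one emirate's registry plus extrapolated rates.

    Each input is a DataFrame with columns ``sex, citizenship, count``.
    Stratum death rates from the registry emirate are applied to the
    other emirates' populations; observed and expected counts are
    returned as one stratified national table.
    """
    deaths = _check_strata("deaths", abu_dhabi_deaths)["count"]
    pop = _check_strata("population", abu_dhabi_pop)["count"]
    other = _check_strata("other population", other_pop)["count"]

    missing = deaths.index.difference(pop.index)
    if len(missing):
        raise ParameterError(f"population table missing strata {list(missing)}")
    missing = other.index.difference(deaths.index)
    if len(missing):
        raise ParameterError(f"death table missing strata {list(missing)}")
    zero_pop = pop.reindex(deaths.index) <= 0
    if (zero_pop & (deaths > 0)).any():
        bad = deaths.index[zero_pop & (deaths > 0)][0]
        raise ParameterError(f"deaths with zero population in stratum {bad}")

    rate = (deaths / pop.reindex(deaths.index).replace(0, np.nan)).fillna(0.0)
    expected = (rate.reindex(other.index) * other).rename("count")

    rows = []
    for (sex, cit), cnt in deaths.items():
        rows.append(dict(endpoint=endpoint, measure="deaths", emirate="abu_dhabi",
                         sex=sex, citizenship=cit, count=float(cnt)))
    for (sex, cit), cnt in expected.items():
        rows.append(dict(endpoint=endpoint, measure="deaths", emirate="other",
                         sex=sex, citizenship=cit, count=float(cnt)))
    return BaselineHealthTable(pd.DataFrame(rows))


def scale_claims(visits: float, coverage: float = 1.0,
                 period_factor: float = 1.0,
                 population_factor: float = 1.0) -> float:
    """Scale raw claim counts to a full-year, full-population estimate.

    ``visits * period_factor / coverage * population_factor`` -- e.g. a
    half-year extract (period_factor 2) from an insurer covering 73% of
    one emirate's population (coverage 0.73), then scaled up to the
    national population.
    """
    if visits < 0:
        raise ParameterError(f"visit count must be >= 0, got {visits}")
    if not 0.0 < coverage <= 1.0:
        raise ParameterError(f"coverage must be in (0, 1], got {coverage}")
    if period_factor <= 0 or population_factor <= 0:
        raise ParameterError("scaling factors must be positive")
    return visits * period_factor / coverage * population_factor
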