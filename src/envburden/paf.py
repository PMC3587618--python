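"""Population-attributable-fraction computation.

The mathematical core of the burden model.  The attributable fraction
compares the prevalence-weighted mean relative risk under the observed
exposure distribution P(x) with the mean under a counterfactual
distribution P'(x) (here: pollutants eliminated to background):

    PAF = (sum_x P(x) RR(x) - sum_x P'(x) RR(x)) / sum_x P(x) RR(x)

with categorical sums including the unexposed reference category at
RR = 1, and continuous exposures integrated over the exposure
distribution.  Per-pollutant fractions acting on one endpoint combine
multiplicatively, PAF = 1 - prod_i (1 - PAF_i), and attributable cases
are PAF times the endpoint's baseline count.

Per-unit relative risks (e.g. per 10 ug/m3, per 100 Bq/m3, per log10
concentration) extrapolate log-linearly; extrapolation is floored at
RR = 1 so that exposure below the counterfactual is never protective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distributions import DistributionSpec, ParameterError

__all__ = [
    "rr_at",
    "paf_categorical",
    "paf_continuous",
    "combine_pafs",
    "attributable_cases",
    "fixed_fraction_attribution",
    "SexSpecificRR",
    "MixtureTerm",
    "Category",
    "COMPLEMENT",
    "RelativeRiskModel",
    "ExposureModel",
    "RiskPair",
]

#: sentinel prevalence: category holds whatever mass the others leave
COMPLEMENT = "complement"


def rr_at(x, rr_unit, unit: float = 1.0, x0=0.0, transform: str = "linear",
          log_floor: float = 1.0):
    """Relative risk at exposure ``x`` from a per-unit RR.

    Returns ``rr_unit ** ((t(x) - t(x0)) / unit)`` where ``t`` is the
    identity or log10 with a concentration floor, floored at 1 (no
    protective extrapolation below the counterfactual ``x0``).
    Broadcasts over array arguments.
    """
    rr_unit = np.asarray(rr_unit, dtype=float)
    if np.any(rr_unit <= 0):
        raise ParameterError("rr_unit must be positive")
    if unit <= 0:
        raise ParameterError(f"unit size must be positive, got {unit}")
    x = np.asarray(x, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if transform == "linear":
        t, t0 = x, x0
    elif transform == "log10":
        t = np.log10(np.maximum(x, log_floor))
        t0 = np.log10(np.maximum(x0, log_floor))
    else:
        raise ParameterError(f"unknown transform {transform!r}")
    rr = rr_unit ** ((t - t0) / unit)
    return np.maximum(rr, 1.0)


def paf_categorical(prevalences, rrs, counterfactual_prevalences=None, axis: int = -1):
    """Attributable fraction for categorical exposure.

    ``prevalences`` and ``rrs`` cover the non-reference categories along
    ``axis``; the implicit reference category carries the remaining mass
    at RR = 1.  The default counterfactual puts all mass in the reference
    category, reducing to sum p(RR-1) / (1 + sum p(RR-1)).
    """
    p = np.asarray(prevalences, dtype=float)
    rr = np.asarray(rrs, dtype=float)
    if np.any(p < -1e-12):
        raise ParameterError("negative prevalence")
    if np.any(rr <= 0):
        raise ParameterError("relative risks must be positive")
    sp = p.sum(axis=axis)
    if np.any(sp > 1.0 + 1e-9):
        raise ParameterError(f"prevalences sum above 1 (max {np.max(sp):.6g})")
    mean_rr = (1.0 - sp) + (p * rr).sum(axis=axis)
    if counterfactual_prevalences is None:
        mean_rr_cf = 1.0
    else:
        cp = np.asarray(counterfactual_prevalences, dtype=float)
        if np.any(cp < -1e-12):
            raise ParameterError("negative counterfactual prevalence")
        scp = cp.sum(axis=axis)
        if np.any(scp > 1.0 + 1e-9):
            raise ParameterError("counterfactual prevalences sum above 1")
        mean_rr_cf = (1.0 - scp) + (cp * rr).sum(axis=axis)
    return (mean_rr - mean_rr_cf) / mean_rr


def paf_continuous(exposure: DistributionSpec, rr_fn,
                   counterfactual: DistributionSpec | None = None,
                   n_points: int = 512) -> float:
    """Attributable fraction for a continuous exposure distribution.

    The relative-risk curve ``rr_fn`` (fixed within one Monte Carlo draw)
    is integrated over the exposure and counterfactual distributions by
    deterministic quadrature on ``n_points`` equiprobable quantile
    midpoints.  A ``None`` counterfactual means RR = 1 (zero exposure).
    """
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    q = (np.arange(n_points) + 0.5) / n_points
    e_exp = float(np.mean(rr_fn(exposure.ppf(q))))
    if not math.isfinite(e_exp) or e_exp <= 0:
        raise ParameterError("quadrature over exposure distribution failed")
    if counterfactual is None:
        e_cf = 1.0
    else:
        e_cf = float(np.mean(rr_fn(counterfactual.ppf(q))))
        if not math.isfinite(e_cf) or e_cf <= 0:
            raise ParameterError("quadrature over counterfactual distribution failed")
    return (e_exp - e_cf) / e_exp


def combine_pafs(pafs, axis: int = 0):
    """Multiplicative-complement combination: 1 - prod(1 - PAF_i).

    Accepts draws in (-1, 1): sampled relative risks whose CI straddles 1
    legitimately produce protective (negative) fractions in some Monte
    Carlo iterations, and the complement product propagates them.
    """
    p = np.asarray(pafs, dtype=float)
    if p.size == 0:
        raise ParameterError("combine_pafs needs at least one PAF")
    if np.any(p >= 1.0):
        raise ParameterError("PAF >= 1 cannot be combined")
    if np.any(p <= -1.0):
        raise ParameterError("PAF <= -1 cannot be combined")
    return 1.0 - np.prod(1.0 - p, axis=axis)


def attributable_cases(paf, d_total):
    """Attributable count: PAF times the baseline count (unrounded)."""
    paf = np.asarray(paf, dtype=float)
    d = np.asarray(d_total, dtype=float)
    if np.any(paf < -1e-9) or np.any(paf > 1.0 + 1e-9):
        raise ParameterError("PAF outside [0, 1]")
    if np.any(d < 0):
        raise ParameterError("baseline count must be non-negative")
    return paf * d


def fixed_fraction_attribution(cases_male: float, cases_female: float,
                               frac_male: float, frac_female: float) -> float:
    """Attribution by fixed sex-specific fractions of observed cases."""
    if cases_male < 0 or cases_female < 0:
        raise ParameterError("case counts must be non-negative")
    for name, f in (("frac_male", frac_male), ("frac_female", frac_female)):
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"{name} outside [0, 1]: {f}")
    return frac_male * cases_male + frac_female * cases_female


# ---------------------------------------------------------------------------
# domain types assembled by the routes registry and consumed by the engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SexSpecificRR:
    """A pair of sex-specific RR specs mixed by the endpoint's sex split."""

    male: DistributionSpec
    female: DistributionSpec
    male_share: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_share <= 1.0:
            raise ParameterError(f"male_share outside [0, 1]: {self.male_share}")


@dataclass(frozen=True)
class MixtureTerm:
    """One weighted component of a mixture prevalence (e.g. citizenship)."""

    weight: float
    dist: DistributionSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ParameterError(f"mixture weight outside [0, 1]: {self.weight}")


@dataclass(frozen=True)
class Category:
    """One non-reference exposure category with its prevalence model.

    ``prevalence`` is a DistributionSpec, the COMPLEMENT sentinel (mass
    left over by the other categories), or a tuple of MixtureTerms whose
    weighted draws sum to the prevalence.
    """

    name: str
    prevalence: object

    def __post_init__(self) -> None:
        p = self.prevalence
        if isinstance(p, DistributionSpec) or p == COMPLEMENT:
            return
        if isinstance(p, tuple) and p and all(isinstance(t, MixtureTerm) for t in p):
            return
        raise ParameterError(
            f"category {self.name!r}: prevalence must be a spec, {COMPLEMENT!r}, "
            "or a tuple of MixtureTerm"
        )


@dataclass(frozen=True)
class RelativeRiskModel:
    """How relative risk responds to exposure for one risk pair.

    ``categorical`` carries one RR spec (or SexSpecificRR) per exposure
    category; ``per_unit_loglinear`` a per-unit RR spec with unit size and
    linear/log10 scale transform; ``fixed_fraction`` sex-specific
    attributable proportions of observed cases.
    """

    form: str
    per_category: tuple = ()
    rr_per_unit: DistributionSpec | None = None
    unit: float = 1.0
    transform: str = "linear"
    log_floor: float = 1.0
    male_fraction: float | None = None
    female_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("categorical", "per_unit_loglinear", "fixed_fraction"):
            raise ParameterError(f"unknown RR form {self.form!r}")
        if self.form == "per_unit_loglinear":
            if self.rr_per_unit is None:
                raise ParameterError("per_unit_loglinear needs rr_per_unit")
            if self.unit <= 0:
                raise ParameterError(f"unit size must be positive, got {self.unit}")
            if self.transform not in ("linear", "log10"):
                raise ParameterError(f"unknown transform {self.transform!r}")
        if self.form == "fixed_fraction":
            for name, f in (("male_fraction", self.male_fraction),
                            ("female_fraction", self.female_fraction)):
                if f is None or not 0.0 <= f <= 1.0:
                    raise ParameterError(f"{name} must be in [0, 1], got {f}")


@dataclass(frozen=True)
class ExposureModel:
    """The population exposure distribution P(x) for one risk pair.

    kind:
      * ``categorical`` -- prevalence categories (two-group water and
        tap-water models are categorical with complement/mixture
        prevalences);
      * ``continuous_scalar`` -- an across-person concentration spec,
        integrated by quadrature within each Monte Carlo draw;
      * ``continuous_spatial`` -- a named population grid with per-cell
        concentration parameters and a background counterfactual;
      * ``seasonal_swim`` -- 12 monthly concentration specs with a
        population swim prevalence and an optional doubled subregion;
      * ``none`` -- no exposure model (fixed-fraction attribution).
    """

    kind: str
    categories: tuple = ()
    counterfactual_prevalences: tuple | None = None
    exposure: DistributionSpec | None = None
    counterfactual: DistributionSpec | None = None
    pollutant: str | None = None
    background: DistributionSpec | None = None
    grid: str | None = None
    monthly: tuple = ()
    month_weights: tuple = ()
    swim_prevalence: float = 0.0
    dubai_share: float = 0.0
    dubai_multiplier: float = 1.0

    def __post_init__(self) -> None:
        kinds = ("categorical", "continuous_scalar", "continuous_spatial",
                 "seasonal_swim", "none")
        if self.kind not in kinds:
            raise ParameterError(f"unknown exposure kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise ParameterError("categorical exposure needs categories")
            n_compl = sum(1 for c in self.categories if c.prevalence == COMPLEMENT)
            if n_compl > 1:
                raise ParameterError("at most one complement category allowed")
        if self.kind == "continuous_scalar" and self.exposure is None:
            raise ParameterError("continuous_scalar exposure needs an exposure spec")
        if self.kind == "continuous_spatial":
            if self.pollutant is None or self.grid is None or self.background is None:
                raise ParameterError(
                    "continuous_spatial exposure needs pollutant, grid and background"
                )
        if self.kind == "seasonal_swim":
            if len(self.monthly) != 12:
                raise ParameterError(
                    f"seasonal_swim needs 12 monthly specs, got {len(self.monthly)}"
                )
            if not 0.0 <= self.swim_prevalence <= 1.0:
                raise ParameterError("swim_prevalence outside [0, 1]")
            if not 0.0 <= self.dubai_share <= 1.0:
                raise ParameterError("dubai_share outside [0, 1]")
            if self.month_weights:
                if len(self.month_weights) != 12:
                    raise ParameterError("month_weights must have 12 entries")
                if abs(sum(self.month_weights) - 1.0) > 1e-9:
                    raise ParameterError("month_weights must sum to 1")


@dataclass(frozen=True)
class RiskPair:
    """One pollutant-to-endpoint link within an exposure route."""

    route: str
    pollutant: str
    endpoint: str
    measure: str
    baseline: float
    exposure: ExposureModel
    rr: RelativeRiskModel
    combine_group: str | None = None
    report_separately: bool = False
    placeholder: bool = False
    cases_male: float = 0.0
    cases_female: float = 0.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.measure not in ("deaths", "visits"):
            raise ParameterError(f"measure must be deaths|visits, got {self.measure!r}")
        if self.baseline < 0:
            raise ParameterError(f"baseline count must be >= 0, got {self.baseline}")
        if self.rr.form == "categorical":
            if len(self.rr.per_category) != len(self.exposure.categories):
                raise ParameterError(
                    f"{self.pollutant}->{self.endpoint}: RR per_category length "
                    f"{len(self.rr.per_category)} != category count "
                    f"{len(self.exposure.categories)}"
                )

    @property
    def key(self) -> str:
        return f"{self.route}/{self.endpoint}/{self.measure}/{self.pollutant}"
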