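"""Monte Carlo orchestration.

Registers every stochastic input of a scenario (relative risks,
prevalences, backgrounds, monthly concentrations), draws one joint
Latin-hypercube sample, evaluates per-iteration attributable fractions
and counts for every risk pair, merges pairs acting on a shared endpoint
multiplicatively, and summarizes draws as mean with 2.5/97.5 percentile
intervals.

Variability within an iteration (across-person concentration
distributions, per-cell spatial noise) is integrated or drawn inside the
iteration; uncertainty (RR and prevalence parameters) is sampled across
iterations.  Every random stream derives deterministically from the root
seed and the variable's full name, so results are independent of pair
ordering and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import (
    DistributionSpec,
    ParameterError,
    Summary,
    sample_lhs,
    substream,
    summarize,
)
from .paf import (
    COMPLEMENT,
    RiskPair,
    SexSpecificRR,
    combine_pafs,
    fixed_fraction_attribution,
    paf_categorical,
    rr_at,
)
from .routes import RouteModel, Scenario, ScenarioError
from .spatial import ExposureGrid, load_grid, truncated_normal_draws

__all__ = [
    "MCConfig",
    "AttributionResult",
    "ScenarioResult",
    "run_route",
    "run_scenario",
    "results_frame",
    "format_count",
    "format_fraction",
]


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings: 1,000 Latin-hypercube iterations by default."""

    iterations: int = 1000
    seed: int = 0
    sampler: str = "lhs"
    quadrature_points: int = 512

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ParameterError(f"iterations must be >= 1, got {self.iterations}")
        if self.sampler not in ("lhs", "srs"):
            raise ParameterError(f"unknown sampler {self.sampler!r}")
        if self.quadrature_points < 1:
            raise ParameterError("quadrature_points must be >= 1")


@dataclass
class AttributionResult:
    """Per route-endpoint draws of PAF and attributable count, with summaries."""

    route: str
    endpoint: str
    measure: str
    pollutants: tuple
    baseline: float
    paf_draws: np.ndarray
    report_separately: bool = False
    is_total: bool = False

    @property
    def count_draws(self) -> np.ndarray:
        return self.paf_draws * self.baseline

    @property
    def paf_summary(self) -> Summary:
        return summarize(self.paf_draws)

    @property
    def count_summary(self) -> Summary:
        return summarize(self.count_draws)

    def to_row(self) -> dict:
        ps, cs = self.paf_summary, self.count_summary
        return {
            "route": self.route,
            "endpoint": self.endpoint,
            "measure": self.measure,
            "pollutants": "+".join(self.pollutants),
            "baseline": self.baseline,
            "attributable_fraction_mean": ps.mean,
            "af_p2.5": ps.p2_5,
            "af_p97.5": ps.p97_5,
            "attributable_count_mean": cs.mean,
            "count_p2.5": cs.p2_5,
            "count_p97.5": cs.p97_5,
            "report_separately": self.report_separately,
            "is_total": self.is_total,
            "display_fraction": format_fraction(ps.mean),
            "display_count": format_count(cs.mean),
            "display_ci": f"{format_count(cs.p2_5)}-{format_count(cs.p97_5)}",
        }


@dataclass
class ScenarioResult:
    """All per-endpoint results plus per-route/measure totals."""

    scenario: str
    mc: MCConfig
    results: list
    totals: list

    @property
    def all_results(self) -> list:
        return list(self.results) + list(self.totals)

    def find(self, route: str, endpoint: str, measure: str,
             include_separate: bool = False) -> AttributionResult:
        for r in self.results:
            if (r.route, r.endpoint, r.measure) == (route, endpoint, measure) \
                    and (include_separate or not r.report_separately):
                return r
        raise KeyError((route, endpoint, measure))

    def total(self, route: str, measure: str) -> AttributionResult:
        for r in self.totals:
            if (r.route, r.measure) == (route, measure):
                return r
        raise KeyError((route, measure))


# ---------------------------------------------------------------------------
# display rounding (kept close to the precision pattern of published tables;
# raw values are always retained alongside)
# ---------------------------------------------------------------------------


def format_count(x: float) -> str:
    x = float(x)
    if x >= 10_000:
        mag = 10 ** (int(np.floor(np.log10(x))) - 2)
        return f"{int(round(x / mag) * mag):,}"
    if x >= 1_000:
        return f"{int(round(x / 10) * 10):,}"
    return f"{int(round(x))}"


def format_fraction(p: float) -> str:
    return f"{100.0 * p:.1f}%"


# ---------------------------------------------------------------------------
# compilation: risk pair -> (registered variables, PAF evaluator)
# ---------------------------------------------------------------------------


@dataclass
class _RunContext:
    mc: MCConfig
    grids: dict


class _CompiledPair:
    def __init__(self, pair: RiskPair):
        self.pair = pair
        self.variables: list = []  # (full name, spec)
        self._build()

    def _var(self, suffix: str, spec: DistributionSpec) -> str:
        name = f"{self.pair.key}/{suffix}"
        self.variables.append((name, spec))
        return name

    def _build(self) -> None:
        pair = self.pair
        kind = pair.exposure.kind
        if kind == "categorical":
            self._build_categorical()
        elif kind == "continuous_scalar":
            self._build_continuous()
        elif kind == "continuous_spatial":
            self._build_spatial()
        elif kind == "seasonal_swim":
            self._build_seasonal()
        elif kind == "none":
            self._build_fixed()
        else:  # pragma: no cover - ExposureModel validates kinds
            raise ParameterError(kind)

    # -- categorical (incl. two-group and mixture prevalences) ----------
    def _build_categorical(self) -> None:
        pair = self.pair
        if pair.rr.form != "categorical":
            raise ScenarioError(
                f"{pair.key}: categorical exposure needs categorical RR form"
            )
        prev_plan = []
        for cat in pair.exposure.categories:
            p = cat.prevalence
            if p == COMPLEMENT:
                prev_plan.append(("complement", None))
            elif isinstance(p, DistributionSpec):
                prev_plan.append(("var", self._var(f"p[{cat.name}]", p)))
            else:  # mixture
                names = [(t.weight, self._var(f"p[{cat.name}]/mix{j}", t.dist))
                         for j, t in enumerate(p)]
                prev_plan.append(("mix", names))
        rr_plan = []
        for cat, entry in zip(pair.exposure.categories, pair.rr.per_category):
            if isinstance(entry, SexSpecificRR):
                nm = self._var(f"rr[{cat.name}]/male", entry.male)
                nf = self._var(f"rr[{cat.name}]/female", entry.female)
                rr_plan.append(("sex", (nm, nf, entry.male_share)))
            else:
                rr_plan.append(("var", self._var(f"rr[{cat.name}]", entry)))
        self._prev_plan, self._rr_plan = prev_plan, rr_plan

    def _eval_categorical(self, cols: dict, ctx: _RunContext) -> np.ndarray:
        n = ctx.mc.iterations
        k = len(self._prev_plan)
        p = np.empty((n, k))
        compl_idx = None
        for i, (tag, payload) in enumerate(self._prev_plan):
            if tag == "complement":
                compl_idx = i
                p[:, i] = 0.0
            elif tag == "var":
                p[:, i] = cols[payload]
            else:
                p[:, i] = sum(w * cols[nm] for w, nm in payload)
        if compl_idx is not None:
            rest = p.sum(axis=1)
            comp = 1.0 - rest
            if np.any(comp < -1e-9):
                raise ParameterError(
                    f"{self.pair.key}: complement prevalence negative"
                )
            p[:, compl_idx] = np.clip(comp, 0.0, 1.0)
        rr = np.empty((n, k))
        for i, (tag, payload) in enumerate(self._rr_plan):
            if tag == "sex":
                nm, nf, share = payload
                rr[:, i] = share * cols[nm] + (1.0 - share) * cols[nf]
            else:
                rr[:, i] = cols[payload]
        cf = self.pair.exposure.counterfactual_prevalences
        return paf_categorical(p, rr, counterfactual_prevalences=cf)

    # -- continuous scalar ----------------------------------------------
    def _build_continuous(self) -> None:
        pair = self.pair
        if pair.rr.form != "per_unit_loglinear":
            raise ScenarioError(
                f"{pair.key}: continuous exposure needs per_unit_loglinear RR"
            )
        self._rr_name = self._var("rr_per_unit", pair.rr.rr_per_unit)

    def _eval_continuous(self, cols: dict, ctx: _RunContext) -> np.ndarray:
        pair = self.pair
        rr_m, exp_m = pair.rr, pair.exposure
        nq = ctx.mc.quadrature_points
        q = (np.arange(nq) + 0.5) / nq
        xq = exp_m.exposure.ppf(q)
        cf = exp_m.counterfactual
        ru = cols[self._rr_name][:, None]
        kw = dict(unit=rr_m.unit, transform=rr_m.transform, log_floor=rr_m.log_floor)
        if cf is None or cf.is_degenerate:
            x0 = 0.0 if cf is None else cf.ppf(np.asarray(0.5)).item()
            e_exp = rr_at(xq[None, :], ru, x0=x0, **kw).mean(axis=1)
            e_cf = 1.0
        else:
            e_exp = rr_at(xq[None, :], ru, x0=0.0, **kw).mean(axis=1)
            e_cf = rr_at(cf.ppf(q)[None, :], ru, x0=0.0, **kw).mean(axis=1)
        return (e_exp - e_cf) / e_exp

    # -- continuous spatial ----------------------------------------------
    def _build_spatial(self) -> None:
        pair = self.pair
        if pair.rr.form != "per_unit_loglinear":
            raise ScenarioError(
                f"{pair.key}: spatial exposure needs per_unit_loglinear RR"
            )
        self._rr_name = self._var("rr_per_unit", pair.rr.rr_per_unit)
        self._bg_name = self._var("background", pair.exposure.background)

    def _eval_spatial(self, cols: dict, ctx: _RunContext) -> np.ndarray:
        pair = self.pair
        grid = ctx.grids.get(pair.exposure.grid)
        if grid is None:
            raise ScenarioError(f"{pair.key}: grid {pair.exposure.grid!r} not resolved")
        w = grid.population_weights()
        mean, sd = grid.concentration_params(pair.exposure.pollutant)
        rng = substream(ctx.mc.seed, f"{pair.key}/cell_noise")
        x = truncated_normal_draws(mean, sd, ctx.mc.iterations, rng)
        rr = rr_at(x, cols[self._rr_name][:, None],
                   unit=pair.rr.unit, x0=cols[self._bg_name][:, None],
                   transform=pair.rr.transform, log_floor=pair.rr.log_floor)
        mean_rr = rr @ w
        return 1.0 - 1.0 / mean_rr

    # -- seasonal swim ----------------------------------------------------
    def _build_seasonal(self) -> None:
        pair = self.pair
        if pair.rr.form != "per_unit_loglinear":
            raise ScenarioError(
                f"{pair.key}: seasonal exposure needs per_unit_loglinear RR"
            )
        self._rr_name = self._var("rr_per_unit", pair.rr.rr_per_unit)
        self._month_names = [
            self._var(f"conc[{i:02d}]", spec)
            for i, spec in enumerate(pair.exposure.monthly)
        ]

    def _eval_seasonal(self, cols: dict, ctx: _RunContext) -> np.ndarray:
        pair = self.pair
        exp_m, rr_m = pair.exposure, pair.rr
        ru = cols[self._rr_name]
        p = exp_m.swim_prevalence
        weights = exp_m.month_weights or tuple([1.0 / 12.0] * 12)
        d = exp_m.dubai_share
        regions = [(1.0 - d, 1.0)]
        if d > 0:
            regions.append((d, exp_m.dubai_multiplier))
        total = np.zeros(ctx.mc.iterations)
        for wm, name in zip(weights, self._month_names):
            c = cols[name]
            for share, factor in regions:
                rr = rr_at(c * factor, ru, unit=rr_m.unit, x0=0.0,
                           transform=rr_m.transform, log_floor=rr_m.log_floor)
                s = p * (rr - 1.0)
                total += wm * share * s / (1.0 + s)
        return total

    # -- fixed fraction ----------------------------------------------------
    def _build_fixed(self) -> None:
        pair = self.pair
        if pair.rr.form != "fixed_fraction":
            raise ScenarioError(f"{pair.key}: exposure kind 'none' needs fixed_fraction RR")
        attributed = fixed_fraction_attribution(
            pair.cases_male, pair.cases_female,
            pair.rr.male_fraction, pair.rr.female_fraction,
        )
        self._fixed_paf = attributed / pair.baseline if pair.baseline > 0 else 0.0

    def evaluate(self, cols: dict, ctx: _RunContext) -> np.ndarray:
        kind = self.pair.exposure.kind
        if kind == "categorical":
            paf = self._eval_categorical(cols, ctx)
        elif kind == "continuous_scalar":
            paf = self._eval_continuous(cols, ctx)
        elif kind == "continuous_spatial":
            paf = self._eval_spatial(cols, ctx)
        elif kind == "seasonal_swim":
            paf = self._eval_seasonal(cols, ctx)
        else:
            paf = np.full(ctx.mc.iterations, self._fixed_paf)
        return np.asarray(paf, dtype=float)


# ---------------------------------------------------------------------------
# grid resolution
# ---------------------------------------------------------------------------


def _resolve_grids(scenario: Scenario, mc: MCConfig,
                   overrides: dict | None = None) -> dict:
    from .synthetic import generate_grid_multi

    grids: dict = {}
    for name, source in scenario.grids.items():
        if overrides and name in overrides:
            source = overrides[name]
        if isinstance(source, ExposureGrid):
            grids[name] = source
        elif isinstance(source, dict) and "object" in source:
            grids[name] = source["object"]
        elif isinstance(source, dict) and "synthetic" in source:
            params = dict(source["synthetic"])
            # grid stands for fixed observational data: one deterministic
            # realization per root seed
            gseed = int(substream(mc.seed, f"grid/{name}").integers(2 ** 31))
            grids[name] = generate_grid_multi(
                n_cells=int(params["n_cells"]),
                pop_total=int(params["pop_total"]),
                pollutant_ranges=params["pollutants"],
                seed=gseed,
                citizen_share=float(params.get("citizen_share", 0.19)),
            )
        elif isinstance(source, str):
            grids[name] = load_grid(source)
        else:
            raise ScenarioError(f"grid {name!r}: unrecognized source {source!r}")
    return grids


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------


def _run_pairs(route: RouteModel, mc: MCConfig, ctx: _RunContext) -> list:
    compiled = [_CompiledPair(p) for p in route.pairs]
    names, specs = [], []
    for cp in compiled:
        for name, spec in cp.variables:
            names.append(name)
            specs.append(spec)
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ScenarioError(f"duplicate variable name {dup!r}")
    sm = sample_lhs(specs, mc.iterations, mc.seed, names=names, method=mc.sampler)
    cols = {name: sm[name] for name in names}

    per_pair = [(cp.pair, cp.evaluate(cols, ctx)) for cp in compiled]

    # merge combination groups multiplicatively; singletons pass through
    results: list = []
    grouped: dict = {}
    order: list = []
    for pair, paf in per_pair:
        gid = pair.combine_group
        key = gid if gid is not None else object()
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append((pair, paf))
    for key in order:
        members = grouped[key]
        pairs = [m[0] for m in members]
        baselines = {p.baseline for p in pairs}
        if len(baselines) > 1:
            raise ScenarioError(
                f"combine group {pairs[0].combine_group!r}: baselines differ {baselines}"
            )
        paf = (members[0][1] if len(members) == 1
               else combine_pafs(np.vstack([m[1] for m in members]), axis=0))
        results.append(AttributionResult(
            route=route.name,
            endpoint=pairs[0].endpoint,
            measure=pairs[0].measure,
            pollutants=tuple(p.pollutant for p in pairs),
            baseline=pairs[0].baseline,
            paf_draws=np.asarray(paf, dtype=float),
            report_separately=any(p.report_separately for p in pairs),
        ))
    return results


def run_route(route: RouteModel, mc: MCConfig,
              grids: dict | None = None) -> list:
    """Evaluate one route; returns one AttributionResult per endpoint."""
    ctx = _RunContext(mc=mc, grids=grids or {})
    return _run_pairs(route, mc, ctx)


def run_scenario(scenario: Scenario, mc: MCConfig,
                 grid_overrides: dict | None = None) -> ScenarioResult:
    """Evaluate every route plus per-route totals (draw-wise sums).

    Separately-reported endpoints (e.g. subpopulation-restricted radon)
    are excluded from route totals, mirroring footnote-style reporting.
    """
    grids = _resolve_grids(scenario, mc, grid_overrides)
    results: list = []
    for route in scenario.routes:
        results.extend(run_route(route, mc, grids=grids))
    totals: list = []
    seen = []
    for r in results:
        if (r.route, r.measure) not in seen:
            seen.append((r.route, r.measure))
    for route_name, measure in seen:
        members = [r for r in results
                   if (r.route, r.measure) == (route_name, measure)
                   and not r.report_separately]
        if len(members) < 2:
            continue
        baseline = sum(m.baseline for m in members)
        count_draws = np.sum([m.count_draws for m in members], axis=0)
        totals.append(AttributionResult(
            route=route_name, endpoint="total", measure=measure,
            pollutants=("all",), baseline=baseline,
            paf_draws=count_draws / baseline if baseline > 0 else count_draws * 0.0,
            is_total=True,
        ))
    return ScenarioResult(scenario=scenario.name, mc=mc,
                          results=results, totals=totals)


def results_frame(result: ScenarioResult) -> pd.DataFrame:
    """Flat summary table: one row per endpoint plus route totals."""
    rows = [r.to_row() for r in result.results] + [t.to_row() for t in result.totals]
    return pd.DataFrame(rows)
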