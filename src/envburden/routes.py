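"""Scenario configuration: exposure routes encoded as risk-pair tables.

A scenario is a YAML (or JSON-compatible) document declaring, per route,
the pollutant-to-endpoint risk pairs: baseline counts, exposure models
and relative-risk models, each with declarative distribution specs.  The
bundled ``uae_2008`` scenario encodes the published parameter tables for
the six routes (outdoor air, indoor air, occupational, drinking water,
coastal water, climate change); validation errors name the offending
route/pair/key path.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .distributions import DistributionSpec, ParameterError
from .paf import (
    COMPLEMENT,
    Category,
    ExposureModel,
    MixtureTerm,
    RelativeRiskModel,
    RiskPair,
    SexSpecificRR,
)

__all__ = [
    "ScenarioError",
    "RouteModel",
    "Scenario",
    "load_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "bundled_scenario_path",
    "load_bundled",
    "build_coastal_model",
    "build_two_group_water_model",
    "build_tap_water_cancer_model",
]

ROUTE_NAMES = ("outdoor_air", "indoor_air", "occupational", "drinking_water",
               "coastal_water", "climate_change")


class ScenarioError(ValueError):
    """A scenario config failed validation; the message names the key path."""


@dataclass(frozen=True)
class RouteModel:
    """One exposure route: a list of risk pairs plus route metadata."""

    name: str
    pairs: tuple
    notes: str = ""

    def __post_init__(self) -> None:
        groups: dict = {}
        for pair in self.pairs:
            if pair.route != self.name:
                raise ScenarioError(
                    f"route {self.name!r}: pair {pair.key} declares route {pair.route!r}"
                )
            if pair.combine_group is not None:
                groups.setdefault(pair.combine_group, []).append(pair)
        for gid, members in groups.items():
            heads = {(m.endpoint, m.measure) for m in members}
            if len(heads) > 1:
                raise ScenarioError(
                    f"route {self.name!r}: combine group {gid!r} mixes endpoints {heads}"
                )


@dataclass(frozen=True)
class Scenario:
    """A fully resolved model scenario."""

    name: str
    routes: tuple
    grids: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    description: str = ""

    @property
    def pairs(self) -> tuple:
        return tuple(p for r in self.routes for p in r.pairs)

    def route(self, name: str) -> RouteModel:
        for r in self.routes:
            if r.name == name:
                return r
        raise KeyError(name)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _dist(node, where: str) -> DistributionSpec:
    if not isinstance(node, dict):
        raise ScenarioError(f"{where}: expected a distribution mapping, got {node!r}")
    try:
        return DistributionSpec.from_dict(node)
    except (ParameterError, KeyError, TypeError) as exc:
        raise ScenarioError(f"{where}: {exc}") from exc


def _prevalence(node, where: str):
    if node == COMPLEMENT:
        return COMPLEMENT
    if isinstance(node, dict) and "mix" in node:
        terms = []
        for j, term in enumerate(node["mix"]):
            if not isinstance(term, dict) or "weight" not in term or "dist" not in term:
                raise ScenarioError(f"{where}/mix[{j}]: need weight and dist")
            terms.append(MixtureTerm(float(term["weight"]),
                                     _dist(term["dist"], f"{where}/mix[{j}]/dist")))
        return tuple(terms)
    return _dist(node, where)


def _rr_entry(node, where: str):
    if isinstance(node, dict) and ("male" in node or "female" in node):
        if "male" not in node or "female" not in node:
            raise ScenarioError(f"{where}: sex-specific RR needs both male and female")
        return SexSpecificRR(
            male=_dist(node["male"], f"{where}/male"),
            female=_dist(node["female"], f"{where}/female"),
            male_share=float(node.get("male_share", 0.5)),
        )
    return _dist(node, where)


def _exposure(node, where: str) -> ExposureModel:
    if not isinstance(node, dict) or "kind" not in node:
        raise ScenarioError(f"{where}: exposure needs a 'kind'")
    kind = node["kind"]
    try:
        if kind == "categorical":
            cats = tuple(
                Category(str(c.get("name", f"cat{i}")),
                         _prevalence(c["prevalence"], f"{where}/categories[{i}]/prevalence"))
                for i, c in enumerate(node.get("categories", ()))
            )
            return ExposureModel(kind="categorical", categories=cats)
        if kind == "continuous_scalar":
            cf = node.get("counterfactual")
            return ExposureModel(
                kind="continuous_scalar",
                exposure=_dist(node["exposure"], f"{where}/exposure"),
                counterfactual=None if cf is None else _dist(cf, f"{where}/counterfactual"),
            )
        if kind == "continuous_spatial":
            return ExposureModel(
                kind="continuous_spatial",
                pollutant=str(node["pollutant"]),
                grid=str(node["grid"]),
                background=_dist(node["background"], f"{where}/background"),
            )
        if kind == "seasonal_swim":
            monthly = node.get("monthly", ())
            if len(monthly) != 12:
                raise ScenarioError(
                    f"{where}/monthly: need 12 entries, got {len(monthly)}"
                )
            specs = tuple(_dist(m, f"{where}/monthly[{i}]") for i, m in enumerate(monthly))
            sp = node.get("swim_prevalence")
            if isinstance(sp, dict):
                prevalence = _swim_prevalence_from_strata(sp, f"{where}/swim_prevalence")
            else:
                prevalence = float(sp)
            return ExposureModel(
                kind="seasonal_swim",
                monthly=specs,
                month_weights=tuple(node.get("month_weights", ())),
                swim_prevalence=prevalence,
                dubai_share=float(node.get("dubai_share", 0.0)),
                dubai_multiplier=float(node.get("dubai_multiplier", 1.0)),
            )
        if kind == "none":
            return ExposureModel(kind="none")
    except KeyError as exc:
        raise ScenarioError(f"{where}: missing key {exc}") from exc
    except ParameterError as exc:
        raise ScenarioError(f"{where}: {exc}") from exc
    raise ScenarioError(f"{where}: unknown exposure kind {kind!r}")


def _swim_prevalence_from_strata(node: dict, where: str) -> float:
    """Population-weighted swim prevalence across demographic strata."""
    try:
        citizen_share = float(node["citizen_share"])
        noncitizen = float(node["noncitizen"])
        strata = node["citizen_strata"]
    except KeyError as exc:
        raise ScenarioError(f"{where}: missing key {exc}") from exc
    total_share = sum(float(s["share"]) for s in strata.values())
    if abs(total_share - 1.0) > 1e-9:
        raise ScenarioError(f"{where}: citizen stratum shares sum to {total_share}, not 1")
    citizen = sum(float(s["share"]) * float(s["prevalence"]) for s in strata.values())
    return citizen_share * citizen + (1.0 - citizen_share) * noncitizen


def _rr(node, where: str) -> RelativeRiskModel:
    if not isinstance(node, dict) or "form" not in node:
        raise ScenarioError(f"{where}: rr needs a 'form'")
    form = node["form"]
    try:
        if form == "categorical":
            per = tuple(_rr_entry(e, f"{where}/per_category[{i}]")
                        for i, e in enumerate(node.get("per_category", ())))
            return RelativeRiskModel(form="categorical", per_category=per)
        if form == "per_unit_loglinear":
            return RelativeRiskModel(
                form="per_unit_loglinear",
                rr_per_unit=_dist(node["rr_per_unit"], f"{where}/rr_per_unit"),
                unit=float(node.get("unit", 1.0)),
                transform=str(node.get("transform", "linear")),
                log_floor=float(node.get("log_floor", 1.0)),
            )
        if form == "fixed_fraction":
            return RelativeRiskModel(
                form="fixed_fraction",
                male_fraction=float(node["male_fraction"]),
                female_fraction=float(node["female_fraction"]),
            )
    except KeyError as exc:
        raise ScenarioError(f"{where}: missing key {exc}") from exc
    except ParameterError as exc:
        raise ScenarioError(f"{where}: {exc}") from exc
    raise ScenarioError(f"{where}: unknown rr form {form!r}")


def _pair(node, route_name: str, where: str) -> RiskPair:
    for key in ("pollutant", "endpoint", "measure", "baseline", "exposure", "rr"):
        if key not in node:
            raise ScenarioError(f"{where}: missing key {key!r}")
    try:
        return RiskPair(
            route=route_name,
            pollutant=str(node["pollutant"]),
            endpoint=str(node["endpoint"]),
            measure=str(node["measure"]),
            baseline=float(node["baseline"]),
            exposure=_exposure(node["exposure"], f"{where}/exposure"),
            rr=_rr(node["rr"], f"{where}/rr"),
            combine_group=node.get("combine_group"),
            report_separately=bool(node.get("report_separately", False)),
            placeholder=bool(node.get("placeholder", False)),
            cases_male=float(node.get("cases_male", 0.0)),
            cases_female=float(node.get("cases_female", 0.0)),
            note=str(node.get("note", "")),
        )
    except ParameterError as exc:
        raise ScenarioError(f"{where}: {exc}") from exc


def scenario_from_dict(doc: dict) -> Scenario:
    if not isinstance(doc, dict):
        raise ScenarioError("scenario document must be a mapping")
    routes = []
    for i, rnode in enumerate(doc.get("routes", ())):
        rname = rnode.get("route")
        where = f"routes[{i}]"
        if rname is None:
            raise ScenarioError(f"{where}: missing key 'route'")
        if rname not in ROUTE_NAMES:
            raise ScenarioError(f"{where}: unknown route {rname!r} (expected one of {ROUTE_NAMES})")
        pairs = tuple(
            _pair(p, rname, f"{where}/risk_pairs[{j}]")
            for j, p in enumerate(rnode.get("risk_pairs", ()))
        )
        routes.append(RouteModel(name=rname, pairs=pairs, notes=str(rnode.get("notes", ""))))
    keys = [p.key for r in routes for p in r.pairs]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ScenarioError(f"duplicate risk pair {dup!r}")
    return Scenario(
        name=str(doc.get("name", "scenario")),
        routes=tuple(routes),
        grids=dict(doc.get("grids", {})),
        population=dict(doc.get("population", {})),
        description=str(doc.get("description", "")),
    )


def load_scenario(path) -> Scenario:
    """Load and validate a scenario config from a YAML/JSON file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        raise ScenarioError(f"scenario file {path} is empty")
    return scenario_from_dict(doc)


# ---------------------------------------------------------------------------
# serialization (canonical form; load(dump(load(x))) == load(x))
# ---------------------------------------------------------------------------


def _prev_to_node(p):
    if p == COMPLEMENT:
        return COMPLEMENT
    if isinstance(p, tuple):
        return {"mix": [{"weight": t.weight, "dist": t.dist.as_dict()} for t in p]}
    return p.as_dict()


def _rr_entry_to_node(e):
    if isinstance(e, SexSpecificRR):
        return {"male": e.male.as_dict(), "female": e.female.as_dict(),
                "male_share": e.male_share}
    return e.as_dict()


def _exposure_to_node(e: ExposureModel) -> dict:
    if e.kind == "categorical":
        return {"kind": "categorical",
                "categories": [{"name": c.name, "prevalence": _prev_to_node(c.prevalence)}
                               for c in e.categories]}
    if e.kind == "continuous_scalar":
        node = {"kind": "continuous_scalar", "exposure": e.exposure.as_dict()}
        if e.counterfactual is not None:
            node["counterfactual"] = e.counterfactual.as_dict()
        return node
    if e.kind == "continuous_spatial":
        return {"kind": "continuous_spatial", "pollutant": e.pollutant,
                "grid": e.grid, "background": e.background.as_dict()}
    if e.kind == "seasonal_swim":
        node = {"kind": "seasonal_swim",
                "monthly": [m.as_dict() for m in e.monthly],
                "swim_prevalence": e.swim_prevalence,
                "dubai_share": e.dubai_share,
                "dubai_multiplier": e.dubai_multiplier}
        if e.month_weights:
            node["month_weights"] = list(e.month_weights)
        return node
    return {"kind": "none"}


def _rr_to_node(rr: RelativeRiskModel) -> dict:
    if rr.form == "categorical":
        return {"form": "categorical",
                "per_category": [_rr_entry_to_node(e) for e in rr.per_category]}
    if rr.form == "per_unit_loglinear":
        return {"form": "per_unit_loglinear", "rr_per_unit": rr.rr_per_unit.as_dict(),
                "unit": rr.unit, "transform": rr.transform, "log_floor": rr.log_floor}
    return {"form": "fixed_fraction", "male_fraction": rr.male_fraction,
            "female_fraction": rr.female_fraction}


def _pair_to_node(p: RiskPair) -> dict:
    node = {"pollutant": p.pollutant, "endpoint": p.endpoint, "measure": p.measure,
            "baseline": p.baseline, "exposure": _exposure_to_node(p.exposure),
            "rr": _rr_to_node(p.rr)}
    if p.combine_group is not None:
        node["combine_group"] = p.combine_group
    if p.report_separately:
        node["report_separately"] = True
    if p.placeholder:
        node["placeholder"] = True
    if p.cases_male or p.cases_female:
        node["cases_male"] = p.cases_male
        node["cases_female"] = p.cases_female
    if p.note:
        node["note"] = p.note
    return node


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "name": s.name,
        "description": s.description,
        "population": dict(s.population),
        "grids": dict(s.grids),
        "routes": [{"route": r.name, "notes": r.notes,
                    "risk_pairs": [_pair_to_node(p) for p in r.pairs]}
                   for r in s.routes],
    }


def bundled_scenario_path() -> str:
    """Filesystem path of the bundled national 2008 scenario."""
    return str(importlib.resources.files("envburden").joinpath("data/uae_2008.yaml"))


def load_bundled() -> Scenario:
    return load_scenario(bundled_scenario_path())


# ---------------------------------------------------------------------------
# builders (programmatic construction of the less-trivial pair shapes)
# ---------------------------------------------------------------------------


def build_two_group_water_model(group1_frac: DistributionSpec,
                                rr_group1: DistributionSpec,
                                rr_group2: DistributionSpec,
                                baseline: float,
                                route: str = "drinking_water",
                                pollutant: str = "water_supply_access",
                                endpoint: str = "gastroenteritis",
                                measure: str = "visits") -> RiskPair:
    """Two-group access model: regulated supply vs unregulated water.

    Group 2 holds the complement of group 1's population fraction; the
    minimal-risk counterfactual puts everyone at RR = 1, giving per-draw
    PAF = (p1(RR1-1) + p2(RR2-1)) / (1 + p1(RR1-1) + p2(RR2-1)).
    """
    exposure = ExposureModel(
        kind="categorical",
        categories=(Category("regulated", group1_frac),
                    Category("unregulated", COMPLEMENT)),
    )
    rr = RelativeRiskModel(form="categorical", per_category=(rr_group1, rr_group2))
    return RiskPair(route=route, pollutant=pollutant, endpoint=endpoint,
                    measure=measure, baseline=baseline, exposure=exposure, rr=rr)


def build_tap_water_cancer_model(citizen_tap: float,
                                 noncitizen_tap: DistributionSpec,
                                 citizen_share: float,
                                 rr_male: DistributionSpec,
                                 rr_female: DistributionSpec,
                                 baseline: float,
                                 endpoint: str,
                                 measure: str,
                                 male_share: float = 0.5,
                                 route: str = "drinking_water") -> RiskPair:
    """Chlorination by-product cancer model with citizenship-mixed tap use.

    The exposed prevalence per draw is ``citizen_share * citizen_tap +
    (1 - citizen_share) * sample(noncitizen_tap)``; the RR mixes
    sex-specific chlorination risks.
    """
    if not 0.0 <= citizen_tap <= 1.0 or not 0.0 <= citizen_share <= 1.0:
        raise ParameterError("proportions must lie in [0, 1]")
    mixture = (MixtureTerm(citizen_share, DistributionSpec.point(citizen_tap)),
               MixtureTerm(1.0 - citizen_share, noncitizen_tap))
    exposure = ExposureModel(kind="categorical",
                             categories=(Category("tap_water", mixture),))
    rr = RelativeRiskModel(
        form="categorical",
        per_category=(SexSpecificRR(rr_male, rr_female, male_share),),
    )
    return RiskPair(route=route, pollutant="chlorination_byproducts",
                    endpoint=endpoint, measure=measure, baseline=baseline,
                    exposure=exposure, rr=rr)


def build_coastal_model(monthly_conc, swim_prev_by_stratum: dict,
                        stratum_weights: dict, noncitizen_prev: float,
                        citizen_share: float, rr_log10: RelativeRiskModel,
                        baseline: float, dubai_share: float = 0.0,
                        dubai_multiplier: float = 2.0,
                        route: str = "coastal_water") -> RiskPair:
    """Seasonal recreational-water model from monthly concentration specs.

    Monthly enterococci specs feed a per-log10 RR among swimmers; the
    swim prevalence is population-weighted over citizen strata and the
    noncitizen share; monthly attributable fractions average with equal
    weights.  A subregion (Dubai) may carry doubled concentrations.
    """
    monthly = tuple(monthly_conc)
    if len(monthly) != 12:
        raise ParameterError(f"need 12 monthly specs, got {len(monthly)}")
    if set(swim_prev_by_stratum) != set(stratum_weights):
        raise ParameterError("stratum prevalence/weight keys differ")
    if abs(sum(stratum_weights.values()) - 1.0) > 1e-9:
        raise ParameterError("stratum weights must sum to 1")
    citizen = sum(stratum_weights[k] * swim_prev_by_stratum[k]
                  for k in stratum_weights)
    prevalence = citizen_share * citizen + (1.0 - citizen_share) * noncitizen_prev
    exposure = ExposureModel(
        kind="seasonal_swim", monthly=monthly, swim_prevalence=prevalence,
        dubai_share=dubai_share, dubai_multiplier=dubai_multiplier,
    )
    return RiskPair(route=route, pollutant="enterococci",
                    endpoint="gastroenteritis", measure="visits",
                    baseline=baseline, exposure=exposure, rr=rr_log10)
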