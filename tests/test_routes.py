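"""Scenario registry: bundled config coverage, validation and builders."""

import numpy as np
import pytest
import yaml

import envburden as eb
from envburden.distributions import DistributionSpec, lognormal_from_median_ci
from envburden.engine import MCConfig, run_route
from envburden.paf import RelativeRiskModel
from envburden.routes import (
    RouteModel,
    Scenario,
    ScenarioError,
    build_coastal_model,
    build_tap_water_cancer_model,
    build_two_group_water_model,
    load_scenario,
    scenario_from_dict,
    scenario_to_dict,
)

# every pollutant-endpoint row the bundled national scenario must encode,
# as (route, pollutant, endpoint, measure)
MANIFEST = [
    ("outdoor_air", "pm25", "all_cause_mortality_over30", "deaths"),
    ("outdoor_air", "pm10", "respiratory_mortality_under5", "deaths"),
    ("outdoor_air", "pm10", "cardiovascular_disease", "visits"),
    ("outdoor_air", "pm10", "respiratory_disease", "visits"),
    ("outdoor_air", "o3", "respiratory_disease", "visits"),
    ("indoor_air", "ets", "cardiovascular_disease", "deaths"),
    ("indoor_air", "ets", "lung_cancer", "deaths"),
    ("indoor_air", "incense", "lung_cancer", "deaths"),
    ("indoor_air", "radon_abu_dhabi_city", "lung_cancer", "deaths"),
    ("indoor_air", "radon_sharjah", "lung_cancer", "deaths"),
    ("indoor_air", "mold", "asthma_under18", "visits"),
    ("indoor_air", "ets", "asthma_under18", "visits"),
    ("indoor_air", "mold", "asthma_adult", "visits"),
    ("indoor_air", "formaldehyde", "asthma_under6", "visits"),
    ("indoor_air", "ets", "cardiovascular_disease", "visits"),
    ("indoor_air", "ets", "lower_respiratory_infection_under6", "visits"),
    ("indoor_air", "ets", "leukemia", "visits"),
    ("indoor_air", "incense", "lung_cancer", "visits"),
    ("indoor_air", "radon_abu_dhabi_city", "lung_cancer", "visits"),
    ("indoor_air", "radon_sharjah", "lung_cancer", "visits"),
    ("occupational", "asbestos", "asbestosis", "deaths"),
    ("occupational", "silica", "silicosis", "deaths"),
    ("occupational", "asbestos", "mesothelioma", "deaths"),
    ("occupational", "benzene_diesel_exhaust", "leukemia", "deaths"),
    ("occupational", "lung_carcinogens", "lung_cancer", "deaths"),
    ("occupational", "asbestos", "asbestosis", "visits"),
    ("occupational", "silica", "silicosis", "visits"),
    ("occupational", "asbestos", "mesothelioma", "visits"),
    ("occupational", "benzene_diesel_exhaust", "leukemia", "visits"),
    ("occupational", "lung_carcinogens", "lung_cancer", "visits"),
    ("drinking_water", "chlorination_byproducts", "bladder_cancer", "deaths"),
    ("drinking_water", "chlorination_byproducts", "colon_cancer", "deaths"),
    ("drinking_water", "chlorination_byproducts", "rectal_cancer", "deaths"),
    ("drinking_water", "water_supply_access", "gastroenteritis", "deaths"),
    ("drinking_water", "chlorination_byproducts", "bladder_cancer", "visits"),
    ("drinking_water", "chlorination_byproducts", "colon_cancer", "visits"),
    ("drinking_water", "chlorination_byproducts", "rectal_cancer", "visits"),
    ("drinking_water", "water_supply_access", "gastroenteritis", "visits"),
    ("coastal_water", "enterococci", "gastroenteritis", "visits"),
    ("climate_change", "temperature_increase", "cardiovascular_disease", "deaths"),
    ("climate_change", "temperature_increase", "cardiovascular_disease", "visits"),
]


class TestBundledScenario:
    def test_six_routes(self, bundled):
        assert [r.name for r in bundled.routes] == [
            "outdoor_air", "indoor_air", "occupational",
            "drinking_water", "coastal_water", "climate_change",
        ]

    def test_every_manifest_row_encoded_exactly_once(self, bundled):
        keys = [(p.route, p.pollutant, p.endpoint, p.measure) for p in bundled.pairs]
        assert sorted(keys) == sorted(MANIFEST)

    def test_combination_groups_stay_within_route_and_endpoint(self, bundled):
        for route in bundled.routes:
            groups = {}
            for p in route.pairs:
                if p.combine_group:
                    groups.setdefault(p.combine_group, []).append(p)
            for members in groups.values():
                assert len({(m.endpoint, m.measure, m.baseline) for m in members}) == 1

    def test_dubai_concentrations_doubled(self, bundled):
        coastal = bundled.route("coastal_water").pairs[0]
        assert coastal.exposure.dubai_multiplier == 2.0
        assert 0.0 < coastal.exposure.dubai_share < 1.0

    def test_swim_prevalence_population_weighted(self, bundled):
        coastal = bundled.route("coastal_water").pairs[0]
        citizen = 0.25 * (0.038 + 0.014 + 0.0087 + 0.0)
        expected = 0.19 * citizen + 0.81 * 0.062
        assert coastal.exposure.swim_prevalence == pytest.approx(expected)

    def test_round_trip_serialization(self, bundled):
        again = scenario_from_dict(scenario_to_dict(bundled))
        assert again == bundled


class TestLoaderValidation:
    def _doc(self, **pair_overrides):
        pair = {
            "pollutant": "x", "endpoint": "e", "measure": "visits",
            "baseline": 100.0,
            "exposure": {"kind": "categorical",
                         "categories": [{"name": "c",
                                         "prevalence": {"kind": "point", "value": 0.2}}]},
            "rr": {"form": "categorical",
                   "per_category": [{"kind": "point", "value": 1.5}]},
        }
        pair.update(pair_overrides)
        return {"name": "t", "routes": [{"route": "indoor_air", "risk_pairs": [pair]}]}

    def test_empty_routes_list_is_valid(self):
        s = scenario_from_dict({"name": "empty", "routes": []})
        assert s.routes == ()

    def test_invalid_triangular_names_the_row(self):
        doc = self._doc(exposure={
            "kind": "categorical",
            "categories": [{"name": "c",
                            "prevalence": {"kind": "triangular",
                                           "lower": 1.0, "mode": 0.9, "upper": 0.5}}],
        })
        with pytest.raises(ScenarioError, match=r"routes\[0\]/risk_pairs\[0\]"):
            scenario_from_dict(doc)

    def test_unknown_distribution_kind_rejected(self):
        doc = self._doc(rr={"form": "categorical",
                            "per_category": [{"kind": "beta", "a": 1, "b": 2}]})
        with pytest.raises(ScenarioError, match="beta"):
            scenario_from_dict(doc)

    def test_missing_key_named(self):
        doc = self._doc()
        del doc["routes"][0]["risk_pairs"][0]["baseline"]
        with pytest.raises(ScenarioError, match="baseline"):
            scenario_from_dict(doc)

    def test_unknown_route_rejected(self):
        doc = self._doc()
        doc["routes"][0]["route"] = "space_weather"
        with pytest.raises(ScenarioError, match="space_weather"):
            scenario_from_dict(doc)

    def test_duplicate_pair_rejected(self):
        doc = self._doc()
        doc["routes"][0]["risk_pairs"].append(doc["routes"][0]["risk_pairs"][0])
        with pytest.raises(ScenarioError, match="duplicate"):
            scenario_from_dict(doc)

    def test_load_scenario_from_file(self, tmp_path):
        path = tmp_path / "s.yaml"
        path.write_text(yaml.safe_dump(self._doc()))
        s = load_scenario(path)
        assert len(s.pairs) == 1


def _run_single(pair, iterations=200, seed=3):
    route = RouteModel(name=pair.route, pairs=(pair,))
    (result,) = run_route(route, MCConfig(iterations=iterations, seed=seed))
    return result


class TestBuilders:
    def test_two_group_point_masses_match_closed_form(self):
        pair = build_two_group_water_model(
            DistributionSpec.point(0.98),
            DistributionSpec.point(2.5),
            DistributionSpec.point(8.7),
            baseline=81_110,
        )
        result = _run_single(pair)
        s = 0.98 * 1.5 + 0.02 * 7.7
        assert np.allclose(result.paf_draws, s / (1 + s))
        assert result.paf_draws[0] == pytest.approx(0.618902, abs=1e-6)

    def test_two_group_degenerate_reference(self):
        pair = build_two_group_water_model(
            DistributionSpec.point(1.0),
            DistributionSpec.point(1.0),
            DistributionSpec.point(9.0),
            baseline=10.0,
        )
        assert np.allclose(_run_single(pair).paf_draws, 0.0)

    def test_tap_water_mixture_prevalence(self):
        pair = build_tap_water_cancer_model(
            citizen_tap=0.105,
            noncitizen_tap=DistributionSpec.point(0.902),
            citizen_share=0.19,
            rr_male=DistributionSpec.point(1.2),
            rr_female=DistributionSpec.point(1.2),
            baseline=929,
            endpoint="bladder_cancer",
            measure="visits",
        )
        result = _run_single(pair)
        prevalence = 0.19 * 0.105 + 0.81 * 0.902
        expected = prevalence * 0.2 / (1 + prevalence * 0.2)
        assert np.allclose(result.paf_draws, expected)
        assert result.paf_draws[0] == pytest.approx(0.130, abs=5e-3)

    def test_tap_water_unit_rr_gives_zero(self):
        pair = build_tap_water_cancer_model(
            0.0, DistributionSpec.point(0.0), 1.0,
            DistributionSpec.point(1.0), DistributionSpec.point(1.0),
            baseline=10, endpoint="bladder_cancer", measure="visits",
        )
        assert np.allclose(_run_single(pair).paf_draws, 0.0)

    def _coastal(self, monthly, p_swim=1.0, dubai_share=0.0):
        strata = {"all": 1.0}
        return build_coastal_model(
            monthly_conc=monthly,
            swim_prev_by_stratum={"all": p_swim},
            stratum_weights=strata,
            noncitizen_prev=p_swim,
            citizen_share=0.5,
            rr_log10=RelativeRiskModel(
                form="per_unit_loglinear",
                rr_per_unit=DistributionSpec.point(1.34),
                unit=1.0, transform="log10", log_floor=1.0,
            ),
            baseline=81_110,
            dubai_share=dubai_share,
        )

    def test_coastal_zero_concentration_below_floor(self):
        pair = self._coastal([DistributionSpec.point(0.0)] * 12)
        assert np.allclose(_run_single(pair).paf_draws, 0.0)

    def test_coastal_single_hot_month_closed_form(self):
        monthly = [DistributionSpec.point(0.0)] * 11 + [DistributionSpec.point(100.0)]
        pair = self._coastal(monthly, p_swim=1.0)
        rr = 1.34**2
        month_paf = (rr - 1) / rr
        assert np.allclose(_run_single(pair).paf_draws, month_paf / 12.0)
        assert month_paf == pytest.approx(0.443083, abs=1e-6)

    def test_coastal_doubling_raises_burden(self):
        monthly = [DistributionSpec.point(10.0)] * 12
        lo = _run_single(self._coastal(monthly, p_swim=0.05, dubai_share=0.0))
        hi = _run_single(self._coastal(monthly, p_swim=0.05, dubai_share=0.5))
        assert hi.paf_draws.mean() > lo.paf_draws.mean()

    def test_coastal_requires_twelve_months(self):
        with pytest.raises(Exception, match="12"):
            self._coastal([DistributionSpec.point(1.0)] * 7)
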