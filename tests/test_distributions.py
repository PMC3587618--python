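"""Distribution specs, parameter conversion and Latin-hypercube sampling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from envburden.distributions import (
    DistributionSpec,
    ParameterError,
    lognormal_from_mean_sd,
    lognormal_from_median_ci,
    sample_lhs,
    summarize,
)

Z = stats.norm.ppf(0.975)


@pytest.mark.parametrize(
    "kind,params",
    [
        ("uniform", (2.0, 1.0)),          # lower > upper
        ("triangular", (0.0, 3.0, 2.0)),  # mode > upper
        ("triangular", (1.0, 0.5, 2.0)),  # mode < lower
        ("lognormal", (0.0, -0.1)),       # sigma < 0
        ("normal", (0.0, -1.0)),          # sd < 0
        ("bernoulli", (1.5,)),            # p > 1
        ("uniform", (0.0, float("nan"))),
    ],
)
def test_invalid_parameters_rejected(kind, params):
    with pytest.raises(ParameterError):
        DistributionSpec(kind, params)


def test_unknown_kind_rejected():
    with pytest.raises(ParameterError, match="kind"):
        DistributionSpec("gamma", (1.0, 1.0))


def test_point_spec_always_returns_value():
    spec = DistributionSpec.point(3.7)
    q = np.linspace(0, 1, 11)
    assert np.all(spec.ppf(q) == 3.7)


@pytest.mark.parametrize(
    "spec,value",
    [
        (DistributionSpec.uniform(5.0, 5.0), 5.0),
        (DistributionSpec.lognormal(math.log(2.0), 0.0), 2.0),
        (DistributionSpec.normal(1.5, 0.0), 1.5),
    ],
)
def test_zero_spread_specs_degenerate_to_point(spec, value):
    assert spec.is_degenerate
    assert np.allclose(spec.ppf(np.linspace(0, 1, 7)), value)


class TestLognormalFromMedianCI:
    def test_closed_form_examples(self):
        spec = lognormal_from_median_ci(1.25, 1.17, 1.32)
        assert spec.param("mu") == pytest.approx(0.223144, abs=1e-6)
        assert spec.param("sigma") == pytest.approx(0.030773, abs=1e-4)
        spec = lognormal_from_median_ci(2.28, 1.15, 4.53)
        assert spec.param("mu") == pytest.approx(0.824175, abs=1e-6)
        assert spec.param("sigma") == pytest.approx(0.349741, abs=1e-5)

    def test_degenerate_ci_gives_point_mass_at_one(self):
        spec = lognormal_from_median_ci(1.0, 1.0, 1.0)
        assert spec.param("mu") == 0.0
        assert spec.param("sigma") == 0.0
        assert spec.ppf(np.asarray(0.31)) == pytest.approx(1.0)

    @given(
        st.floats(0.5, 5.0),
        st.floats(1.05, 4.0),
        st.floats(1.05, 4.0),
    )
    def test_quantiles_reproduce_symmetric_ci(self, median, r_lo, r_hi):
        """With a log-symmetric CI the 2.5/97.5 quantiles recover the bounds."""
        ratio = math.sqrt(r_lo * r_hi)
        lcl, ucl = median / ratio, median * ratio
        spec = lognormal_from_median_ci(median, lcl, ucl)
        assert spec.median() == pytest.approx(median, rel=1e-9)
        got = spec.ppf(np.array([0.025, 0.975]))
        assert got[0] == pytest.approx(lcl, rel=1e-6)
        assert got[1] == pytest.approx(ucl, rel=1e-6)

    @pytest.mark.parametrize(
        "args", [(-1.0, 1.0, 2.0), (1.0, -1.0, 2.0), (1.0, 2.0, 1.5), (3.0, 1.0, 2.0)]
    )
    def test_invalid_bounds_rejected(self, args):
        with pytest.raises(ParameterError):
            lognormal_from_median_ci(*args)

    def test_median_outside_ci_allowed_when_flagged(self):
        spec = lognormal_from_median_ci(1.08, 1.13, 1.16, require_median_in_ci=False)
        assert spec.median() == pytest.approx(1.08)
        assert spec.param("sigma") == pytest.approx(math.log(1.16 / 1.13) / (2 * Z))


class TestLognormalFromMeanSd:
    @pytest.mark.parametrize("mean,sd", [(14.4, 7.37), (22.5, 63.6), (3.0, 0.5)])
    def test_moments_recovered(self, mean, sd):
        spec = lognormal_from_mean_sd(mean, sd)
        mu, sigma = spec.params
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-9)
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-9)

    def test_radon_example_parameters(self):
        spec = lognormal_from_mean_sd(14.4, 7.37)
        assert spec.param("mu") == pytest.approx(2.550900, abs=1e-5)
        assert spec.param("sigma") == pytest.approx(0.482342, abs=1e-5)

    def test_zero_sd_is_point_mass(self):
        spec = lognormal_from_mean_sd(5.0, 0.0)
        assert spec.is_degenerate
        assert spec.ppf(np.asarray(0.9)) == pytest.approx(5.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ParameterError, match="mean"):
            lognormal_from_mean_sd(0.0, 1.0)


class TestLatinHypercube:
    def test_stratification_uniform(self):
        sm = sample_lhs([DistributionSpec.uniform(0, 1)], n=4, seed=7)
        strata = np.floor(np.sort(sm.draws[:, 0]) * 4).astype(int)
        assert list(strata) == [0, 1, 2, 3]

    def test_stratification_holds_for_every_kind(self):
        specs = [
            DistributionSpec.uniform(2, 9),
            DistributionSpec.triangular(0, 2, 10),
            DistributionSpec.lognormal(0.5, 0.8),
            DistributionSpec.normal(-1, 2),
        ]
        n = 64
        sm = sample_lhs(specs, n=n, seed=3)
        for j, spec in enumerate(specs):
            u = spec.cdf(sm.draws[:, j])
            assert sorted(np.floor(u * n).astype(int).tolist()) == list(range(n))

    def test_point_spec_constant(self):
        sm = sample_lhs([DistributionSpec.point(3.7)], n=100, seed=0)
        assert np.all(sm.draws == 3.7)

    def test_lognormal_sample_median(self):
        sm = sample_lhs([DistributionSpec.lognormal(0.0, 0.5)], n=10_000, seed=5)
        assert np.median(sm.draws) == pytest.approx(1.0, rel=0.02)

    def test_seed_reproducibility(self):
        specs = [DistributionSpec.uniform(0, 1), DistributionSpec.normal(0, 1)]
        a = sample_lhs(specs, n=50, seed=11, names=["u", "z"])
        b = sample_lhs(specs, n=50, seed=11, names=["u", "z"])
        assert np.array_equal(a.draws, b.draws)
        c = sample_lhs(specs, n=50, seed=12, names=["u", "z"])
        assert not np.array_equal(a.draws, c.draws)

    def test_adding_a_variable_does_not_perturb_others(self):
        u = DistributionSpec.uniform(0, 1)
        a = sample_lhs([u], n=40, seed=4, names=["a"])
        b = sample_lhs([u, u], n=40, seed=4, names=["a", "b"])
        assert np.array_equal(a.draws[:, 0], b.draws[:, 0])

    def test_invalid_arguments(self):
        with pytest.raises(ParameterError):
            sample_lhs([DistributionSpec.point(1)], n=0, seed=0)
        with pytest.raises(ParameterError):
            sample_lhs([DistributionSpec.point(1)] * 2, n=5, seed=0, names=["x", "x"])

    def test_truncation_respected_and_stratified(self):
        spec = DistributionSpec.normal(0.0, 1.0, truncate_lower=0.5)
        sm = sample_lhs([spec], n=500, seed=9)
        x = sm.draws[:, 0]
        assert np.all(x >= 0.5)
        # mean of a normal truncated at a: mu + sd * phi(a)/(1-Phi(a))
        expected = stats.norm.pdf(0.5) / stats.norm.sf(0.5)
        assert np.mean(x) == pytest.approx(expected, rel=0.02)

    def test_lhs_and_srs_means_agree(self):
        spec = DistributionSpec.lognormal(0.2, 0.6)
        n = 4000
        lhs = sample_lhs([spec], n=n, seed=2).draws[:, 0]
        srs = sample_lhs([spec], n=n, seed=2, method="srs").draws[:, 0]
        se = math.sqrt(np.var(lhs) / n + np.var(srs) / n)
        assert abs(np.mean(lhs) - np.mean(srs)) < 3 * se

    def test_lhs_mean_variance_beats_srs(self):
        """Over 50 seed replicates the LHS mean estimator has lower variance."""
        spec = DistributionSpec.uniform(0, 1)
        n = 64
        lhs_means = [np.mean(sample_lhs([spec], n, seed=s).draws)
                     for s in range(50)]
        srs_means = [np.mean(sample_lhs([spec], n, seed=s, method="srs").draws)
                     for s in range(50)]
        assert np.var(lhs_means) < np.var(srs_means)


class TestSummarize:
    def test_constant_vector(self):
        s = summarize(np.full(20, 4.2))
        assert (s.mean, s.p2_5, s.p97_5) == (pytest.approx(4.2),) * 3

    def test_linear_interpolation_convention(self):
        s = summarize(np.arange(1, 1001, dtype=float))
        assert s.mean == pytest.approx(500.5)
        assert s.p2_5 == pytest.approx(25.975)
        assert s.p97_5 == pytest.approx(975.025)

    def test_normal_draw_quantiles(self):
        x = sample_lhs([DistributionSpec.normal(0, 1)], n=100_000, seed=1).draws
        s = summarize(x)
        assert s.p2_5 == pytest.approx(-1.96, abs=0.05)
        assert s.p97_5 == pytest.approx(1.96, abs=0.05)

    def test_empty_vector_rejected(self):
        with pytest.raises(ParameterError):
            summarize([])
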