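"""Distribution solving, registry validation, and realization modes."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from ipfcea import (
    ConfigError,
    DistributionSpec,
    default_registry,
    load_registry,
    solve_beta_mean_sd,
    solve_lognormal,
)
from ipfcea.parameters import default_config_text


class TestSolveLognormal:
    def test_closed_form_example(self):
        mu, sigma = solve_lognormal(42373, 34482)
        assert mu == pytest.approx(math.log(34482), rel=1e-12)
        assert sigma == pytest.approx(math.sqrt(2 * math.log(42373 / 34482)), rel=1e-12)
        assert mu == pytest.approx(10.448, abs=5e-4)
        assert sigma == pytest.approx(0.642, abs=5e-4)

    def test_degenerate_point_mass(self):
        mu, sigma = solve_lognormal(7.5, 7.5)
        assert sigma == 0.0
        assert math.exp(mu) == pytest.approx(7.5)

    @pytest.mark.parametrize("mean,median", [(4900, 5000), (-1, 1), (1, -1), (0, 0)])
    def test_invalid_inputs(self, mean, median):
        with pytest.raises(ConfigError):
            solve_lognormal(mean, median)

    @given(
        median=st.floats(0.1, 1e6),
        ratio=st.floats(1.0, 3.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_roundtrip_reproduces_summaries(self, median, ratio):
        mean = median * ratio
        mu, sigma = solve_lognormal(mean, median)
        assert math.exp(mu) == pytest.approx(median, rel=1e-9)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-9)


class TestSolveBetaMeanSd:
    @pytest.mark.parametrize(
        "mean,sd,alpha,beta",
        [(0.75, 0.15, 5.50, 1.833), (0.064, 0.02, 9.52, 139.2)],
    )
    def test_method_of_moments_examples(self, mean, sd, alpha, beta):
        a, b = solve_beta_mean_sd(mean, sd)
        assert a == pytest.approx(alpha, abs=0.01)
        assert b == pytest.approx(beta, abs=0.1)
        # moments round-trip
        assert a / (a + b) == pytest.approx(mean, rel=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-9)

    @pytest.mark.parametrize("mean,sd", [(0.5, 0.5), (0.5, 0.6), (0.0, 0.1), (1.0, 0.1)])
    def test_no_beta_exists(self, mean, sd):
        with pytest.raises(ConfigError):
            solve_beta_mean_sd(mean, sd)


class TestMonteCarloRecovery:
    """1e6-draw sampling recovers the stated summaries within 3 standard errors."""

    N = 1_000_000

    def _draws(self, spec):
        return np.asarray(spec.distribution.sample(np.random.default_rng(42), self.N))

    def test_lognormal_rows_mean_and_median(self, registry):
        for spec in registry:
            if spec.distribution.family != "lognormal":
                continue
            x = self._draws(spec)
            g = spec.distribution.given
            se_mean = x.std(ddof=1) / math.sqrt(self.N)
            assert abs(x.mean() - g["mean"]) <= 3 * se_mean, spec.name
            # SE of the sample median: 1 / (2 f(median) sqrt(n))
            mu, sigma = spec.distribution.shape
            f_med = 1.0 / (g["median"] * sigma * math.sqrt(2 * math.pi))
            se_med = 1.0 / (2 * f_med * math.sqrt(self.N))
            assert abs(np.median(x) - g["median"]) <= 3 * se_med, spec.name

    def test_beta_rows_mean_and_sd(self, registry):
        for spec in registry:
            if spec.distribution.family != "beta":
                continue
            x = self._draws(spec)
            assert ((x >= 0) & (x <= 1)).all(), spec.name
            mean = spec.distribution.mean()
            se_mean = x.std(ddof=1) / math.sqrt(self.N)
            assert abs(x.mean() - mean) <= 3 * se_mean, spec.name
            if spec.distribution.parameterization == "mean_sd":
                sd = spec.distribution.given["sd"]
                # asymptotic SE of the sample SD via the fourth central moment
                m4 = np.mean((x - x.mean()) ** 4)
                se_sd = math.sqrt(max(m4 - sd**4, 0) / (4 * sd**2 * self.N))
                assert abs(x.std(ddof=1) - sd) <= 3 * se_sd, spec.name

    def test_truncated_normal_stays_in_support(self, registry):
        from scipy import stats

        spec = registry["u_complication"]
        x = self._draws(spec)
        assert (x >= 0).all()
        # mean of the 0-truncated normal (the truncation point is 3 SD below
        # the location, so the shift is ~4e-5)
        expected = stats.truncnorm.mean(-3.0, np.inf, loc=0.03, scale=0.01)
        se = x.std(ddof=1) / math.sqrt(self.N)
        assert abs(x.mean() - expected) <= 3 * se


class TestRegistry:
    def test_default_registry_matches_published_inputs(self, registry):
        assert registry["sens_biopsy"].distribution.shape == (27.0, 7.0)
        assert registry["prevalence"].distribution.shape == (626.0, 922.0)
        assert registry["c_treat"].base_value == 711_579
        assert registry["c_slb"].base_value == 42_373
        assert registry["u_biopsy"].psa_fixed
        assert registry["p_fp_benefit_test"].psa_fixed
        assert registry["p_fp_benefit_treatall"].psa_fixed
        for spec in registry:
            assert spec.range_low <= spec.base_value <= spec.range_high

    def test_base_outside_range_rejected(self):
        cfg = yaml.safe_load(default_config_text())
        for row in cfg["parameters"]:
            if row["name"] == "c_treat":
                row["base"] = 950_000
        with pytest.raises(ConfigError, match="c_treat"):
            load_registry(cfg)

    def test_missing_symbol_named_in_error(self):
        cfg = yaml.safe_load(default_config_text())
        cfg["parameters"] = [r for r in cfg["parameters"] if r["name"] != "prevalence"]
        with pytest.raises(ConfigError, match="prevalence"):
            load_registry(cfg)

    def test_unsolvable_distribution_named_in_error(self):
        cfg = yaml.safe_load(default_config_text())
        for row in cfg["parameters"]:
            if row["name"] == "p_referral":
                row["dist"] = {
                    "family": "beta", "parameterization": "mean_sd",
                    "mean": 0.5, "sd": 0.9,
                }
        with pytest.raises(ConfigError, match="p_referral"):
            load_registry(cfg)


class TestRealize:
    def test_base_point(self, registry):
        p = registry.realize("base")
        assert p.sens_biopsy == 0.75
        assert p.c_treat == 711_579
        assert p.treat_cost_multiplier == 1.0
        assert p.p_inconclusive_treat == 0.0

    def test_distribution_mean_point(self, registry):
        p = registry.realize("distribution_mean")
        assert p.sens_biopsy == pytest.approx(27 / 34)
        assert p.prevalence == pytest.approx(626 / 1548)
        assert p.c_treat == pytest.approx(711_579, rel=1e-12)
        # fixed rows sit at base even at the mean point
        assert p.u_biopsy == 0.013

    def test_sample_is_seed_deterministic(self, registry):
        a = registry.realize("sample", rng=np.random.default_rng(7))
        b = registry.realize("sample", rng=np.random.default_rng(7))
        assert a == b

    def test_sample_requires_rng_and_valid_mode(self, registry):
        with pytest.raises(ConfigError):
            registry.realize("sample")
        with pytest.raises(ConfigError):
            registry.realize("bogus")

    def test_fixed_rows_never_vary_and_draws_are_valid(self, random_parameter_sets):
        for p in random_parameter_sets:
            assert p.u_biopsy == 0.013
            assert p.p_fp_benefit_test == 0.0
            assert p.p_fp_benefit_treatall == 0.0
            for name in ("p_referral", "sens_algo", "spec_algo", "sens_gc",
                         "spec_gc", "p_biopsy_death", "sens_biopsy",
                         "spec_biopsy", "prevalence"):
                assert 0.0 <= getattr(p, name) <= 1.0
            for name in ("c_algo", "c_classifier", "c_bronch", "c_slb",
                         "c_symptom", "c_treat"):
                assert getattr(p, name) > 0
            assert p.u_complication >= 0
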