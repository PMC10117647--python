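"""Tests for random-search calibration and derived carcinogenic profiles."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from fieldsim import (CancerProfile, ModelParameters, ParameterRanges,
                      PENALTY_OBJECTIVE, evaluate_candidate, hits_regression,
                      in_silico_cohort, integrated_mutation_rate, km_estimate,
                      load_profiles, percentile_times, sample_parameters,
                      synthesize_cohort, turnover_per_month)


def base_params(**kw):
    kw.setdefault("N", 100)
    kw.setdefault("rS", 3.0)
    kw.setdefault("dS", 1.5)
    kw.setdefault("max_time", 400.0)
    return ModelParameters(**kw)


class TestSampleParameters:
    def test_degenerate_ranges_return_exact_values(self, rng):
        r = ParameterRanges(r1=(1.05, 1.05), rS1=(0.9, 0.9), rS=(3, 3),
                            dS=(1.5, 1.5), log10_mu1=(-3, -3),
                            log10_muS1=(-4, -4), log10_muS=(-2, -2))
        p = sample_parameters(r, rng, base_params())
        assert (p.r1, p.rS1, p.rS, p.dS) == (1.05, 0.9, 3.0, 1.5)
        assert (p.mu1, p.muS1, p.muS) == (1e-3, 1e-4, 1e-2)

    def test_inverted_bounds_error(self):
        with pytest.raises(ValueError):
            ParameterRanges(r1=(1.2, 0.8))

    def test_seed_reproducible(self):
        a = sample_parameters(ParameterRanges(), np.random.default_rng(9),
                              base_params())
        b = sample_parameters(ParameterRanges(), np.random.default_rng(9),
                              base_params())
        assert a == b

    @pytest.mark.filterwarnings("ignore:rS <= dS")
    def test_draws_within_bounds_and_log_uniform(self, rng):
        r = ParameterRanges()
        draws = [sample_parameters(r, rng, base_params()) for _ in range(2000)]
        r1 = np.array([p.r1 for p in draws])
        lmu = np.log10([p.muS for p in draws])
        assert r1.min() >= r.r1[0] and r1.max() <= r.r1[1]
        assert lmu.min() >= r.log10_muS[0] and lmu.max() <= r.log10_muS[1]
        # log10 mu uniform on its range
        _, p_ks = stats.kstest(lmu, stats.uniform(-5, 3).cdf)
        assert p_ks > 0.01


class TestEvaluateCandidate:
    def clinical_grid(self, params, n=400, seed=77):
        cohort = in_silico_cohort(params, n_runs=n, rng=seed)
        return percentile_times(km_estimate(cohort))

    def test_self_fit_is_near_zero(self):
        p = base_params(mu1=1e-2, muS1=1e-2, muS=1e-2)
        grid = self.clinical_grid(p)
        obj = evaluate_candidate(p, grid, n_runs=200, rng=5)
        assert obj < 0.05

    def test_non_initiating_candidate_penalised(self):
        p = base_params(mu1=0.0, max_time=30.0)
        grid = self.clinical_grid(base_params(mu1=1e-2, muS1=1e-2, muS=1e-2))
        assert evaluate_candidate(p, grid, n_runs=25, rng=5) == PENALTY_OBJECTIVE

    def test_deterministic_given_seed(self):
        p = base_params(mu1=1e-2, muS1=1e-2, muS=1e-2)
        grid = self.clinical_grid(p, n=100)
        assert (evaluate_candidate(p, grid, n_runs=50, rng=3)
                == evaluate_candidate(p, grid, n_runs=50, rng=3))

    def test_too_few_runs_error(self):
        p = base_params()
        grid = self.clinical_grid(base_params(mu1=1e-2, muS1=1e-2, muS=1e-2),
                                  n=100)
        with pytest.raises(ValueError):
            evaluate_candidate(p, grid, n_runs=10, rng=1)


class TestSynthesizeCohort:
    def truth(self):
        return base_params(mu1=1e-2, muS1=1e-2, muS=1e-2)

    def test_no_censoring_all_events(self):
        s = synthesize_cohort(self.truth(), 30, censor_fraction=0.0, rng=4)
        assert s.events.all()

    def test_censor_fraction_applied(self):
        s = synthesize_cohort(self.truth(), 40, censor_fraction=0.25, rng=4)
        assert (~s.events).sum() == 10
        assert len(s) == 40

    def test_seed_reproducible_table(self):
        a = synthesize_cohort(self.truth(), 20, 0.1, rng=8).to_frame()
        b = synthesize_cohort(self.truth(), 20, 0.1, rng=8).to_frame()
        assert a.equals(b)

    def test_validation(self):
        with pytest.raises(ValueError):
            synthesize_cohort(self.truth(), 0, rng=1)
        with pytest.raises(ValueError):
            synthesize_cohort(self.truth(), 10, censor_fraction=1.0, rng=1)


class TestDerivedQuantities:
    def profile(self, **kw):
        defaults = dict(code="X", name="x", source="s", SQ=0.5, r1=1.0,
                        rS1=1.0, rS=3.0, dS=2.0, log10_mu1=-3.0,
                        log10_muS1=-3.0, log10_muS=-3.0, log10_muI=-9.0,
                        p_value=0.5)
        defaults.update(kw)
        return CancerProfile(**defaults)

    def test_integrated_rate_sums_log10_components(self):
        fx = {p.code: p for p in load_profiles()}
        assert integrated_mutation_rate(fx["ACC"]) == pytest.approx(-10.197)
        assert integrated_mutation_rate(fx["COAD"]) == pytest.approx(-10.575)
        assert integrated_mutation_rate(
            self.profile(log10_mu1=0.0, log10_muS1=0.0, log10_muS=0.0)) == 0.0

    def test_missing_component_errors(self):
        with pytest.raises(ValueError):
            integrated_mutation_rate(self.profile(log10_mu1=float("nan")))

    def test_turnover_per_month(self):
        fx = {p.code: p for p in load_profiles()}
        assert turnover_per_month(fx["KICH"]) == pytest.approx(1.558)
        assert turnover_per_month(fx["BLCA"]) == pytest.approx(3.939)
        assert turnover_per_month(self.profile(dS=0.0)) == 0.0


class TestHitsRegression:
    def test_exact_line(self):
        reg = hits_regression([(-10, 3), (-9, 4), (-8, 5)])
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(13.0)
        assert reg.predict(-7.0) == pytest.approx(6.0)

    def test_insufficient_points(self):
        with pytest.raises(ValueError):
            hits_regression([(-10, 3), (-9, 4)])

    def test_constant_x(self):
        with pytest.raises(ValueError):
            hits_regression([(-9, 3), (-9, 4), (-9, 5)])

    def test_null_slope_p_roughly_uniform(self, rng):
        # independent y: slope p values should not concentrate near 0
        ps = []
        x = rng.normal(size=20)
        for _ in range(300):
            y = rng.normal(size=20)
            ps.append(hits_regression(list(zip(x, y))).p_value)
        _, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01
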