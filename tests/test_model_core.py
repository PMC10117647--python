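"""Unit and property tests for the well-mixed hybrid engine."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fieldsim import (DivisionOutcome, FrozenTissueError, ModelParameters,
                      TissueState, TumorState, apply_surgery,
                      deterministic_growth_time, division_distribution,
                      event_channel_probabilities, proportion_bin, run_full,
                      simulate_to_detection, turnover_step, waiting_time)


def params(**kw):
    kw.setdefault("N", 1000)
    return ModelParameters(**kw)


class TestParameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(N=1)
        with pytest.raises(ValueError):
            params(mu1=1.5)
        with pytest.raises(ValueError):
            params(d=-1.0)
        with pytest.raises(ValueError):
            params(detection_threshold=1500.0)  # <= hybrid_switch * N

    def test_subcritical_tumor_warns(self):
        with pytest.warns(UserWarning, match="no net growth"):
            params(rS=1.0, dS=1.0)


class TestEventAlgebra:
    def test_waiting_time_pure_tissue(self):
        assert waiting_time(params(d=1.0), 0) == pytest.approx(1e-3)

    def test_waiting_time_with_tumor(self):
        p = params(d=1.0, rS=1.5, dS=1.0)
        assert waiting_time(p, 1000) == pytest.approx(1.0 / 3500.0)

    def test_zero_total_rate_is_frozen(self):
        with pytest.raises(FrozenTissueError):
            waiting_time(params(d=0.0), 0)

    def test_channels_no_tumor(self):
        assert event_channel_probabilities(params(), 0) == (1.0, 0.0, 0.0)

    def test_channels_hand_example(self):
        p = params(d=1.0, rS=1.5, dS=1.0)
        probs = event_channel_probabilities(p, 1000)
        assert probs == pytest.approx((1000 / 3500, 1500 / 3500, 1000 / 3500))

    @given(d=st.floats(0.1, 10), rS=st.floats(1.0, 5), dS=st.floats(0, 0.9),
           XS=st.integers(0, 10 ** 6))
    def test_channels_normalized(self, d, rS, dS, XS):
        probs = event_channel_probabilities(params(d=d, rS=rS, dS=dS), XS)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)


class TestDivisionDistribution:
    def test_pure_type0_no_mutation(self):
        p = division_distribution(TissueState(1000, 0, 0), params())
        assert p[DivisionOutcome.DAUGHTER_TYPE0] == 1.0

    def test_neutral_symmetry(self):
        st_ = TissueState(500, 300, 200)
        p = division_distribution(st_, params())
        assert p[:3] == pytest.approx([0.5, 0.3, 0.2])
        assert p[3] == 0.0

    def test_hand_example(self):
        # F = 1*500 + 1.2*300 + 0.8*200 = 1020
        st_ = TissueState(500, 300, 200)
        pr = params(r1=1.2, rS1=0.8, mu1=0.01, muS1=0.01, muS=0.001)
        p = division_distribution(st_, pr)
        assert p == pytest.approx(np.array([495.0, 361.4, 163.44, 0.16]) / 1020)

    def test_empty_tissue_fitness_errors(self):
        with pytest.raises(FrozenTissueError):
            division_distribution(TissueState(0, 0, 1000), params(rS1=0.0))

    @given(x0=st.integers(0, 500), x1=st.integers(0, 500),
           xs1=st.integers(1, 500),
           r1=st.floats(0.1, 3), rs1=st.floats(0.1, 3),
           mu1=st.floats(0, 1), mus1=st.floats(0, 1), mus=st.floats(0, 1))
    def test_normalized(self, x0, x1, xs1, r1, rs1, mu1, mus1, mus):
        if x0 + x1 + xs1 < 2:
            return
        st_ = TissueState(x0, x1, xs1)
        pr = ModelParameters(N=st_.N, r1=r1, rS1=rs1,
                             mu1=mu1, muS1=mus1, muS=mus)
        assert division_distribution(st_, pr).sum() == pytest.approx(
            1.0, abs=1e-12)


class TestTurnover:
    def test_no_mutation_homogeneous_is_invariant(self, rng):
        pr = params(N=50)
        st_ = TissueState(50, 0, 0)
        tumor = TumorState()
        for _ in range(100):
            st_, tumor = turnover_step(st_, tumor, pr, rng)
        assert (st_.X0, st_.X1, st_.XS1) == (50, 0, 0)
        assert tumor.XS == 0

    def test_conservation_under_randomized_steps(self, rng):
        pr = ModelParameters(N=30, r1=1.3, rS1=0.7, mu1=0.05, muS1=0.05,
                             muS=0.02)
        st_ = TissueState(10, 10, 10)
        tumor = TumorState()
        for _ in range(5000):
            st_, tumor = turnover_step(st_, tumor, pr, rng)
            assert st_.N == 30
        assert tumor.XS >= 0

    def test_neutral_drift_fixation_probability(self, rng):
        # with no mutation and equal fitness, a clone of size k fixes
        # with probability k/N (classical Moran result)
        N, k, runs = 10, 3, 20_000
        pr = ModelParameters(N=N)
        fixed = 0
        for _ in range(runs):
            st_ = TissueState(N - k, k, 0)
            tumor = TumorState()
            while 0 < st_.X1 < N:
                st_, tumor = turnover_step(st_, tumor, pr, rng)
            fixed += st_.X1 == N
        phat = fixed / runs
        se = math.sqrt(phat * (1 - phat) / runs)
        assert abs(phat - k / N) < 3 * se + 1e-12


class TestDeterministicGrowth:
    def test_hand_example(self):
        t = deterministic_growth_time(1.5, 1.0, 1000, 1e9)
        assert t == pytest.approx(2.0 * math.log(5e5))

    def test_threshold_at_switch_is_zero(self):
        assert deterministic_growth_time(1.5, 1.0, 1000, 2000) == 0.0

    def test_no_net_growth_errors(self):
        with pytest.raises(ValueError):
            deterministic_growth_time(1.0, 1.0, 1000, 1e9)
        with pytest.raises(ValueError):
            deterministic_growth_time(1.5, 1.0, 1000, 1999)


class TestSurgery:
    def test_resection_zeroes_tumor(self):
        assert apply_surgery(TumorState(XS=1e9, t=50.0)) == TumorState(0.0, 50.0)

    def test_idempotent(self):
        t = TumorState(0.0, 3.0)
        assert apply_surgery(t) == t


class TestWholeRuns:
    def test_blocked_pathway_censors(self):
        pr = params(N=100, mu1=0.0, muS1=0.01, muS=0.01, max_time=50.0)
        out = run_full(pr, rng=3)
        assert not out.detected and not out.recurred
        assert out.t_detect == pr.max_time
        assert out.composition_at_surgery is None

    def test_detected_run_conserves_tissue(self):
        pr = params(N=200, mu1=0.01, muS1=0.01, muS=0.01)
        res = simulate_to_detection(pr, rng=5)
        assert res.detected
        assert res.composition.N == 200

    def test_fixed_seed_replays_bit_identically(self):
        pr = params(N=100, mu1=0.01, muS1=0.01, muS=0.01)
        assert run_full(pr, rng=11) == run_full(pr, rng=11)

    def test_mean_detection_time_self_consistent(self):
        # small-N mean detection time against a larger reference batch
        pr = params(N=50, mu1=0.05, muS1=0.05, muS=0.05)
        t_small = [simulate_to_detection(pr, rng=s).t_detect
                   for s in range(400)]
        t_ref = [simulate_to_detection(pr, rng=10_000 + s).t_detect
                 for s in range(2000)]
        se = np.std(t_small, ddof=1) / math.sqrt(len(t_small))
        assert abs(np.mean(t_small) - np.mean(t_ref)) < 3 * se


class TestProportionBin:
    @pytest.mark.parametrize("xs1,expected", [
        (100, "small"), (101, "intermediate"), (500, "intermediate"),
        (900, "intermediate"), (901, "large"),
    ])
    def test_boundaries(self, xs1, expected):
        comp = TissueState(1000 - xs1, 0, xs1)
        assert proportion_bin(comp, 1000) == expected
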