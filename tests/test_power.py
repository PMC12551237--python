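"""Design sizing: noncentral-t oracle values, Monte-Carlo brackets, inputs."""

import numpy as np
import pytest

from sctrials.models.reference import (
    BiasedOraclePredictor,
    NoisyOraclePredictor,
    OraclePredictor,
)
from sctrials.power import (
    DesignParams,
    arm_compare,
    bootstrap_design,
    estimate_design_inputs,
    monte_carlo_power,
    paired_n,
    power_paired,
    power_two_sample,
    two_sample_n,
)


def P(delta=5.0, sd=10.0, alpha=0.05, power=0.8):
    return DesignParams(delta, sd, alpha, power)


class TestSampleSizes:
    @pytest.mark.parametrize("sd,expected", [(10.0, 34), (20.0, 128), (5.0, 10)])
    def test_paired_sizes(self, sd, expected):
        assert paired_n(P(sd=sd)) == expected

    @pytest.mark.parametrize(
        "delta,sd,expected", [(5.0, 10.0, 64), (4.0, 5.0, 26), (5.0, 20.0, 253)]
    )
    def test_two_sample_sizes(self, delta, sd, expected):
        assert two_sample_n(P(delta=delta, sd=sd)) == expected

    def test_doubling_sd_roughly_quadruples_n(self):
        ratio = two_sample_n(P(sd=20.0)) / two_sample_n(P(sd=10.0))
        assert 3.9 <= ratio <= 4.0

    def test_returned_n_is_smallest(self):
        for sd in (5.0, 10.0):
            n = paired_n(P(sd=sd))
            assert power_paired(n, P(sd=sd)) >= 0.8
            assert power_paired(n - 1, P(sd=sd)) < 0.8
        n2 = two_sample_n(P())
        assert power_two_sample(n2, P()) >= 0.8 > power_two_sample(n2 - 1, P())

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower, TTestPower

        for d in (0.25, 0.5, 1.0):
            sm = TTestPower().solve_power(effect_size=d, alpha=0.05, power=0.8)
            assert paired_n(P(delta=d, sd=1.0)) == int(np.ceil(sm))
            sm2 = TTestIndPower().solve_power(effect_size=d, alpha=0.05, power=0.8)
            assert two_sample_n(P(delta=d, sd=1.0)) == int(np.ceil(sm2))

    def test_paired_with_sqrt2_sd_matches_two_sample_asymptotically(self):
        n_paired = paired_n(P(sd=10.0 * np.sqrt(2.0)))
        assert abs(n_paired - two_sample_n(P(sd=10.0))) <= 2

    def test_single_arm_total_below_rct_total_when_pairing_helps(self):
        for delta in (3.0, 5.0):
            for sd in (8.0, 12.0):
                for ratio in (0.6, 1.0, 1.3):
                    sd_paired = ratio * sd
                    single = paired_n(P(delta=delta, sd=sd_paired))
                    total = 2 * two_sample_n(P(delta=delta, sd=sd))
                    if sd_paired < sd * np.sqrt(2.0):
                        assert single < total

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            DesignParams(delta=0.0, sd=1.0)
        with pytest.raises(ValueError):
            DesignParams(delta=1.0, sd=1.0, alpha=1.5)


class TestMonteCarloPower:
    @pytest.mark.parametrize(
        "design,n_fn", [("paired", paired_n), ("two_sample", two_sample_n)]
    )
    def test_power_bracketing_at_returned_n(self, design, n_fn):
        p = P()
        n = n_fn(p)
        hi = monte_carlo_power(n, p, design=design, n_reps=40_000, seed=1)
        lo = monte_carlo_power(n - 1, p, design=design, n_reps=40_000, seed=2)
        assert 0.79 <= hi <= 0.83
        assert lo < 0.80


class TestDesignInputs:
    def test_oracle_gives_zero_paired_sd(self, small_instances):
        di = estimate_design_inputs(small_instances, OraclePredictor())
        assert di.sd_paired == 0.0 and di.bias == 0.0
        assert di.sd_two_sample > 0

    def test_unbiased_noise_recovers_its_own_sd(self):
        from sctrials.cohort import default_emsci_config, generate_cohort

        inst = generate_cohort(default_emsci_config(n_patients=2000, seed=31)).instances()
        sigma = 0.5
        di = estimate_design_inputs(inst, NoisyOraclePredictor(sigma, seed=8))
        # UEMS sums 10 independent per-score noises -> sd = sigma * sqrt(10)
        assert di.sd_paired == pytest.approx(sigma * np.sqrt(10), rel=0.08)
        assert abs(di.bias) < 0.15 and not di.bias_flagged

    def test_constant_shift_is_flagged_as_bias_not_variance(self, small_instances):
        di = estimate_design_inputs(small_instances, BiasedOraclePredictor(0.4))
        assert di.sd_paired == pytest.approx(0.0, abs=1e-9)
        assert di.bias == pytest.approx(-4.0)  # 10 UEMS coordinates x 0.4
        assert di.bias_flagged

    def test_too_few_instances_rejected(self, small_instances):
        with pytest.raises(ValueError):
            estimate_design_inputs(small_instances[:2], OraclePredictor())


class TestBootstrapDesign:
    def test_reproducible_and_contains_point_estimate(self, small_instances):
        pred = NoisyOraclePredictor(1.0, seed=3)
        b1 = bootstrap_design(small_instances, pred, P(), n_boot=200, seed=4)
        b2 = bootstrap_design(small_instances, pred, P(), n_boot=200, seed=4)
        assert b1 == b2
        di = estimate_design_inputs(small_instances, pred)
        point = paired_n(P(sd=di.sd_paired))
        assert b1["single_arm_n"]["p2.5"] <= point <= b1["single_arm_n"]["p97.5"]
        assert b1["degenerate_resamples"] == 0

    def test_small_n_boot_rejected(self, small_instances):
        with pytest.raises(ValueError):
            bootstrap_design(small_instances, OraclePredictor(), P(), n_boot=10)


class TestArmCompare:
    def test_identical_groups_two_sample(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = arm_compare(g, g.copy(), paired=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.test_type == "two-sample"

    def test_paired_constant_difference(self):
        rng = np.random.default_rng(0)
        b = rng.normal(10, 3, 40)
        res = arm_compare(b + 1.5, b, paired=True)
        assert res.mean_a - res.mean_b == pytest.approx(1.5)
        assert res.p_value < 1e-6
        assert "paired" in res.summary()

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            arm_compare([1.0, 2.0], [1.0], paired=True)
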