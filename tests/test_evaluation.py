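"""Benchmark metrics: worked cases, brute-force oracle, summaries, importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sctrials.evaluation import (
    InstanceError,
    aggregate_by_distance,
    importance,
    mean_residual_bl_nli,
    patient_folds,
    rmse_bl_nli,
    summarize,
    time_profile,
)
from sctrials.levels import (
    KEY_MUSCLE_LEVELS,
    SIDES,
    ExcludedPatientError,
    myotomes_below_nli,
)
from sctrials.models.base import ModelSpec, fit


def brute_force_errors(pred, obs, nli):
    """Independent oracle: explicit loop over the below-NLI coordinates."""
    key_row = {lev: i for i, lev in enumerate(KEY_MUSCLE_LEVELS)}
    side_col = {s: j for j, s in enumerate(SIDES)}
    sq, total, n = 0.0, 0.0, 0
    pred = np.asarray(pred).reshape(10, 2)
    obs = np.asarray(obs).reshape(10, 2)
    for lev, side in myotomes_below_nli(nli):
        d = pred[key_row[lev], side_col[side]] - obs[key_row[lev], side_col[side]]
        sq += d * d
        total += d
        n += 1
    return np.sqrt(sq / n), total / n


class TestMetricWorkedCases:
    def test_perfect_prediction_is_zero(self):
        obs = np.random.default_rng(0).integers(0, 6, 20).astype(float)
        assert rmse_bl_nli(obs, obs, "C6") == 0.0
        assert mean_residual_bl_nli(obs, obs, "C6") == 0.0

    def test_c6_four_unit_residuals(self):
        # NLI C6 -> 16 coordinates; |pred - obs| = 1 at 4 of them
        obs = np.zeros(20)
        pred = np.zeros(20)
        idx = [2 * KEY_MUSCLE_LEVELS.index(l) for l in ("C7", "C8", "L2", "S1")]
        pred[idx] = 1.0
        assert rmse_bl_nli(pred, obs, "C6") == pytest.approx(0.5)

    def test_t6_single_residual_of_two(self):
        obs = np.zeros(20)
        pred = np.zeros(20)
        pred[2 * KEY_MUSCLE_LEVELS.index("L4")] = 2.0
        assert rmse_bl_nli(pred, obs, "T6") == pytest.approx(np.sqrt(4 / 10))

    def test_constant_and_balanced_residuals(self):
        obs = np.full(20, 2.0)
        assert mean_residual_bl_nli(obs + 0.5, obs, "T6") == pytest.approx(0.5)
        pred = obs.copy()
        pred[2 * KEY_MUSCLE_LEVELS.index("L2")] += 1  # left
        pred[2 * KEY_MUSCLE_LEVELS.index("L3")] -= 1
        assert mean_residual_bl_nli(pred, obs, "L1") == pytest.approx(0.0)

    def test_sacral_nli_excluded(self):
        with pytest.raises(ExcludedPatientError):
            rmse_bl_nli(np.zeros(20), np.zeros(20), "S1")


def test_metrics_agree_with_bruteforce_on_random_cases():
    rng = np.random.default_rng(99)
    for _ in range(200):
        pred = rng.uniform(0, 5, 20)
        obs = rng.integers(0, 6, 20).astype(float)
        nli = KEY_MUSCLE_LEVELS[rng.integers(0, 9)]  # rostral to S1
        r_ref, m_ref = brute_force_errors(pred, obs, nli)
        assert abs(rmse_bl_nli(pred, obs, nli) - r_ref) < 1e-12
        assert abs(mean_residual_bl_nli(pred, obs, nli) - m_ref) < 1e-12


class TestSummarize:
    def test_single_error_degenerate_percentiles(self):
        s = summarize([InstanceError(0.5, 0.1, 10, "B")])
        piv = s.set_index(["stratum", "statistic"])["value"]
        assert piv[("all", "median")] == 0.5
        assert piv[("all", "p2.5")] == 0.5 and piv[("all", "p97.5")] == 0.5

    def test_median_of_integer_ladder(self):
        errs = [InstanceError(float(k), 0.0, 1, "A") for k in range(101)]
        s = summarize(errs, by_ais=False)
        assert s.set_index("statistic")["value"]["median"] == 50.0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_percentile_ordering_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.exponential(1.0, size=30)
        errs = [InstanceError(v, 0.0, 1, "A") for v in vals]
        s1 = summarize(errs, by_ais=False).set_index("statistic")["value"]
        assert s1["p2.5"] <= s1["median"] <= s1["p97.5"]
        perm = [errs[i] for i in rng.permutation(30)]
        s2 = summarize(perm, by_ais=False).set_index("statistic")["value"]
        assert s1.equals(s2)

    def test_empty_stratum_absent_not_zero(self):
        errs = [InstanceError(1.0, 0.0, 1, "A"), InstanceError(2.0, 0.0, 1, "C")]
        s = summarize(errs)
        assert set(s["stratum"]) == {"all", "A", "C"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestTimeProfile:
    def test_constant_errors_give_constant_curve(self):
        errs = [InstanceError(0.7, 0, d, "A") for d in range(10, 30) for _ in (0, 1)]
        curve = time_profile(errs)
        assert np.allclose(curve.to_numpy(), 0.7)

    def test_linearly_decreasing_errors_give_nonincreasing_curve(self):
        errs = [InstanceError(3.0 - 0.1 * d, 0, d, "A") for d in range(25)]
        vals = time_profile(errs).to_numpy()
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_single_day_of_data(self):
        curve = time_profile([InstanceError(1.0, 0, 12, "A")])
        assert list(curve.index) == [12] and curve.iloc[0] == 1.0


def test_patient_folds_keep_patients_together(small_instances):
    rng = np.random.default_rng(0)
    folds = patient_folds(small_instances, 5, rng)
    df = pd.DataFrame(
        {"pid": [i.patient_id for i in small_instances], "fold": folds}
    )
    assert (df.groupby("pid")["fold"].nunique() == 1).all()
    assert set(folds) == set(range(5))
    with pytest.raises(ValueError):
        patient_folds(small_instances[:3], 5, rng)


def test_oracle_predictions_give_all_zero_summary(small_instances):
    errs = [
        InstanceError(
            rmse_bl_nli(i.late.motor.reshape(-1), i.late, i.early.nli),
            mean_residual_bl_nli(i.late.motor.reshape(-1), i.late, i.early.nli),
            i.early.dai, i.early.ais,
        )
        for i in small_instances
    ]
    s = summarize(errs, by_ais=False)
    assert (s.set_index("statistic")["value"][["median", "p2.5", "p97.5"]] == 0).all()


class TestImportance:
    @pytest.fixture(scope="class")
    def ridge_importance(self, small_instances):
        model = fit(ModelSpec("linear_regularized", {}, 0), small_instances[:120])
        table = importance(
            model, small_instances[120:], ("L3", "left"), n_repeats=3, seed=0
        )
        return table

    def test_ranks_are_a_permutation(self, ridge_importance):
        assert sorted(ridge_importance["rank"]) == list(range(1, 72))
        assert (ridge_importance["backend"] == "permutation").all()

    def test_features_ignored_by_construction_score_zero(self, small_instances):
        model = fit(ModelSpec("carry_forward", {}, 0), small_instances[:50])
        table = importance(
            model, small_instances[120:150], ("L3", "left"), n_repeats=2, seed=1
        )
        ignored = table[~table["feature"].str.startswith("ms_")]
        assert (ignored["score"] == 0.0).all()
        own = float(table.set_index("feature").loc["ms_left_L3", "score"])
        assert own > 0

    def test_aggregation_partitions_all_features(self, ridge_importance):
        agg = aggregate_by_distance(ridge_importance)
        assert agg["n_features"].sum() == 71
        seq = agg[agg["kind"] == "sequence"]
        assert seq["n_features"].sum() == 60
        # the endpoint's own cell exists at distance zero
        own = seq[(seq["distance"] == 0) & (seq["laterality"] == "ipsilateral")
                  & (seq["modality"] == "MS")]
        assert len(own) == 1 and own["n_features"].iloc[0] == 1

    def test_proximal_ipsilateral_motor_dominates(self, ridge_importance):
        agg = aggregate_by_distance(ridge_importance)
        seq = agg[agg["kind"] == "sequence"]
        own = seq[(seq["distance"] == 0) & (seq["laterality"] == "ipsilateral")
                  & (seq["modality"] == "MS")]["mean_rank"].iloc[0]
        assert own == seq["mean_rank"].min()
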