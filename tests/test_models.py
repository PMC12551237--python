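"""Model fitting contracts: determinism, clipping, persistence, uncertainty."""

import numpy as np
import pytest

from sctrials.features import target_batch
from sctrials.models.base import (
    MODEL_FAMILIES,
    ModelSpec,
    Prediction,
    fit,
    load_model,
    perturb_predict,
    predict,
    predict_batch,
    save_model,
)
from sctrials.models.api import SegmentalRecoveryModel

from conftest import make_pair


@pytest.fixture(scope="module")
def train_test(small_instances):
    return small_instances[:120], small_instances[120:140]


NEURAL = ("conv_sequence", "seq2seq_attention", "graph_sequence")
_HP = {fam: {"epochs": 8} for fam in NEURAL}


@pytest.mark.parametrize("family", sorted(MODEL_FAMILIES))
def test_every_family_predicts_in_score_range(family, train_test):
    train, test = train_test
    model = fit(ModelSpec(family, _HP.get(family, {}), seed=0), train)
    preds = predict_batch(model, test)
    assert preds.shape == (len(test), 20)
    assert (preds >= 0).all() and (preds <= 5).all()


def test_constant_target_linear_fit_predicts_constant(train_test):
    import dataclasses

    train, test = train_test
    const = []
    for inst in train:
        late = dataclasses.replace(
            inst.late, motor=np.full((10, 2), 3, dtype=np.int16)
        )
        const.append(dataclasses.replace(inst, late=late))
    model = fit(ModelSpec("linear_regularized", {}, 0), const)
    preds = predict_batch(model, test)
    assert preds == pytest.approx(np.full((len(test), 20), 3.0), abs=1e-6)


def test_same_spec_seed_data_reproduces_predictions(train_test):
    train, test = train_test
    spec = ModelSpec("conv_sequence", {"epochs": 5}, seed=11)
    p1 = predict_batch(fit(spec, train), test)
    p2 = predict_batch(fit(spec, train), test)
    assert np.array_equal(p1, p2)


@pytest.mark.parametrize("family", ["linear_regularized", "conv_sequence"])
def test_prediction_invariant_to_training_row_order(family, train_test):
    train, test = train_test
    spec = ModelSpec(family, _HP.get(family, {}), seed=3)
    rng = np.random.default_rng(0)
    shuffled = [train[i] for i in rng.permutation(len(train))]
    p1 = predict_batch(fit(spec, train), test)
    p2 = predict_batch(fit(spec, shuffled), test)
    assert np.allclose(p1, p2)


def test_training_loss_decreases(train_test):
    train, _ = train_test
    model = fit(ModelSpec("conv_sequence", {"epochs": 15}, seed=0), train)
    curve = model.loss_curve_
    assert len(curve) == 15 and curve[-1] < curve[0]


def test_single_patient_training_refused():
    rec = make_pair(pid="only")
    from sctrials.assessment import benchmark_inclusion

    instances = benchmark_inclusion([rec])
    with pytest.raises(ValueError, match="two patients"):
        fit(ModelSpec("linear_regularized", {}, 0), instances)
    with pytest.raises(ValueError, match="empty"):
        fit(ModelSpec("linear_regularized", {}, 0), [])


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="unknown model family"):
        ModelSpec("deep_thought", {}, 0)


def test_carry_forward_returns_early_scores(train_test):
    train, test = train_test
    model = fit(ModelSpec("carry_forward", {}, 0), train)
    preds = predict_batch(model, test)
    expected = np.stack([i.early.motor.reshape(-1).astype(float) for i in test])
    assert np.array_equal(preds, expected)


@pytest.mark.parametrize("family", ["conv_sequence", "gradient_boosted_trees"])
def test_persistence_round_trip(tmp_path, family, train_test):
    train, test = train_test
    model = fit(ModelSpec(family, _HP.get(family, {}), seed=2), train)
    save_model(model, tmp_path / "m")
    reloaded = load_model(tmp_path / "m")
    assert np.allclose(predict_batch(model, test), predict_batch(reloaded, test))
    assert reloaded.spec == model.spec


def test_schema_mismatch_raises(train_test):
    train, test = train_test
    model = fit(ModelSpec("carry_forward", {}, 0), train)
    model.training_manifest["schema_version"] = "fe-0"
    with pytest.raises(ValueError, match="schema"):
        predict_batch(model, test)


class TestPerturbPredict:
    def test_zero_perturbation_collapses_band(self, train_test):
        train, test = train_test
        model = fit(ModelSpec("linear_regularized", {}, 0), train)
        pred = perturb_predict(model, test[0], n_reps=20, perturb_prob=0.0)
        assert pred.lower == pytest.approx(pred.motor_pred)
        assert pred.upper == pytest.approx(pred.motor_pred)

    def test_band_brackets_point_and_is_reproducible(self, train_test):
        train, test = train_test
        model = fit(ModelSpec("linear_regularized", {}, 0), train)
        p1 = perturb_predict(model, test[1], n_reps=30, perturb_prob=0.2,
                             rng=np.random.default_rng(5))
        p2 = perturb_predict(model, test[1], n_reps=30, perturb_prob=0.2,
                             rng=np.random.default_rng(5))
        assert (p1.lower <= p1.motor_pred + 1e-12).all()
        assert (p1.motor_pred <= p1.upper + 1e-12).all()
        assert np.array_equal(p1.lower, p2.lower) and np.array_equal(p1.upper, p2.upper)

    def test_too_few_reps_rejected(self, train_test):
        train, test = train_test
        model = fit(ModelSpec("carry_forward", {}, 0), train)
        with pytest.raises(ValueError):
            perturb_predict(model, test[0], n_reps=1)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            Prediction(np.full(20, 2.0), lower=np.full(20, 3.0), upper=np.full(20, 4.0))


class TestModelResultsAPI:
    def test_fit_cv_summary_reports_held_out_errors(self, small_instances):
        model = SegmentalRecoveryModel(
            small_instances, family="linear_regularized", seed=1
        )
        res = model.fit_cv(n_folds=3)
        assert res.cv_errors_ is not None and len(res.cv_errors_) == len(small_instances)
        assert res.median_rmse_bl_nli_ >= 0
        text = res.summary()
        assert "linear_regularized" in text and "Held-out" in text

    def test_simulation_pool_overlap_rejected(self, small_instances):
        res = SegmentalRecoveryModel(
            small_instances[:100], family="carry_forward"
        ).fit()
        with pytest.raises(ValueError, match="disjoint"):
            res.simulate_trials(small_instances)

    def test_oracle_targets_round_trip(self, small_instances):
        y = target_batch(small_instances[:3])
        assert y.shape == (3, 20)
        assert y[0, 0] == small_instances[0].late.motor[0, 0]
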