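"""Model specification, fitting, prediction and persistence.

A :class:`ModelSpec` names one of the benchmark families; :func:`fit` trains
it on a list of analysis pairs and returns a :class:`FittedModel` whose
predictions are deterministic given its parameters and input.  Predictions
are continuous on the 0-5 motor scale (the benchmark evaluates unrounded
scores) and clipped to the valid range.  :func:`perturb_predict` propagates
assessment uncertainty by re-predicting under random +/-1 jitters of the
input scores and reporting per-coordinate 2.5/97.5 percentile bands.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ..assessment import Instance
from ..features import SCHEMA_VERSION, encode_batch, target_batch
from .neural import ConvSequenceNet, GraphSequenceNet, Seq2SeqAttentionNet
from .sklearn_models import GradientBoostedFamily, RandomForestFamily, RidgeFamily

__all__ = [
    "MODEL_FAMILIES", "ModelSpec", "Prediction", "FittedModel",
    "fit", "predict", "predict_batch", "perturb_predict",
    "save_model", "load_model",
]


class _CarryForwardFamily:
    """No-recovery reference: predicted late scores equal the early scores."""

    def __init__(self, hyperparams=None):
        self.hp = {}

    def fit(self, X_seq, X_scal, y, rng):
        return self

    def predict(self, X_seq, X_scal):
        n = X_seq.shape[0]
        out = np.empty((n, 20))
        out[:, 0::2] = X_seq[:, 0, :] * 5.0  # left motor channel
        out[:, 1::2] = X_seq[:, 1, :] * 5.0  # right motor channel
        return out


#: The benchmark families plus the carry-forward reference null.
MODEL_FAMILIES = {
    "linear_regularized": RidgeFamily,
    "random_forest": RandomForestFamily,
    "gradient_boosted_trees": GradientBoostedFamily,
    "conv_sequence": ConvSequenceNet,
    "seq2seq_attention": Seq2SeqAttentionNet,
    "graph_sequence": GraphSequenceNet,
    "carry_forward": _CarryForwardFamily,
}


@dataclass(frozen=True)
class ModelSpec:
    """Family name, hyperparameter overrides, and the experiment seed."""

    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; "
                f"choose from {sorted(MODEL_FAMILIES)}"
            )


@dataclass
class Prediction:
    """Predicted motor scores (20 coordinates) with an optional band."""

    motor_pred: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.motor_pred = np.clip(np.asarray(self.motor_pred, float), 0.0, 5.0)
        if (self.lower is None) != (self.upper is None):
            raise ValueError("band must provide both bounds or neither")
        if self.lower is not None:
            if not (np.all(self.lower <= self.motor_pred + 1e-12)
                    and np.all(self.motor_pred <= self.upper + 1e-12)):
                raise ValueError("uncertainty band must bracket the point prediction")


@dataclass
class FittedModel:
    """A trained family with its spec and training manifest."""

    spec: ModelSpec
    impl: object
    training_manifest: dict

    def predict_batch(self, instances: Sequence[Instance]) -> np.ndarray:
        return predict_batch(self, instances)

    @property
    def loss_curve_(self) -> list[float]:
        return getattr(self.impl, "loss_curve_", [])


def _canonical_order(instances: Sequence[Instance]) -> list[Instance]:
    # training is invariant to the row order of the input table
    return sorted(instances, key=lambda i: (i.patient_id, i.early.dai, i.late.dai))


def fit(spec: ModelSpec, train: Sequence[Instance]) -> FittedModel:
    """Train ``spec`` on the given instances (seed-reproducible)."""
    if len(train) == 0:
        raise ValueError("training set is empty")
    patients = {i.patient_id for i in train}
    if len(patients) < 2:
        raise ValueError(
            "training requires instances from at least two patients; "
            f"got {len(patients)}"
        )
    train = _canonical_order(train)
    X_seq, X_scal = encode_batch(train)
    y = target_batch(train)
    rng = np.random.default_rng(spec.seed)
    impl = MODEL_FAMILIES[spec.family](spec.hyperparams).fit(X_seq, X_scal, y, rng)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_instances": len(train),
        "n_patients": len(patients),
        "seed": spec.seed,
    }
    return FittedModel(spec=spec, impl=impl, training_manifest=manifest)


def predict_batch(model: FittedModel, instances: Sequence[Instance]) -> np.ndarray:
    """Clipped (n, 20) motor predictions for a batch of instances."""
    if model.training_manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            "feature schema mismatch: model trained with "
            f"{model.training_manifest.get('schema_version')!r}, "
            f"current is {SCHEMA_VERSION!r}"
        )
    X_seq, X_scal = encode_batch(instances)
    return np.clip(model.impl.predict(X_seq, X_scal), 0.0, 5.0)


def predict(model: FittedModel, instance: Instance) -> Prediction:
    return Prediction(motor_pred=predict_batch(model, [instance])[0])


def _jitter_assessment(a, rng: np.random.Generator, prob: float):
    """Random +/-1 jitter of every score with the given probability."""
    def jit(arr, high):
        flips = rng.random(arr.shape) < prob
        signs = rng.choice([-1, 1], size=arr.shape)
        return np.clip(arr + flips * signs, 0, high).astype(np.int16)

    import dataclasses
    return dataclasses.replace(
        a, motor=jit(a.motor, 5),
        light_touch=jit(a.light_touch, 2), pinprick=jit(a.pinprick, 2),
    )


def perturb_predict(
    model: FittedModel,
    instance: Instance,
    n_reps: int = 30,
    perturb_prob: float = 0.1,
    rng: np.random.Generator | None = None,
) -> Prediction:
    """Prediction with an input-uncertainty band.

    Each of the ``n_reps`` repetitions jitters every motor and sensory score
    of the acute assessment by +/-1 with probability ``perturb_prob``
    (re-clipped to the valid range), mimicking inter-rater assessment
    uncertainty.  The band is the per-coordinate 2.5/97.5 percentile of the
    perturbed predictions (the unperturbed prediction included); the point
    estimate is the unperturbed prediction.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(0)
    import dataclasses
    variants = [instance]
    for _ in range(n_reps):
        variants.append(
            dataclasses.replace(instance, early=_jitter_assessment(instance.early, rng, perturb_prob))
        )
    preds = predict_batch(model, variants)
    # percentile interpolation may fall inside the sample range; the band is
    # defined to bracket the unperturbed point prediction
    lower = np.minimum(np.percentile(preds, 2.5, axis=0), preds[0])
    upper = np.maximum(np.percentile(preds, 97.5, axis=0), preds[0])
    return Prediction(motor_pred=preds[0], lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# Persistence: a directory with a YAML spec + manifest and a parameter blob
# ---------------------------------------------------------------------------

def save_model(model: FittedModel, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "family": model.spec.family,
        "hyperparams": dict(model.spec.hyperparams),
        "seed": model.spec.seed,
        "manifest": model.training_manifest,
    }
    (path / "model.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    with open(path / "params.pkl", "wb") as fh:
        pickle.dump(model.impl, fh)
    return path


def load_model(path: str | Path) -> FittedModel:
    path = Path(path)
    meta = yaml.safe_load((path / "model.yaml").read_text())
    if meta["manifest"].get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"cannot load model: schema {meta['manifest'].get('schema_version')!r} "
            f"does not match current {SCHEMA_VERSION!r}"
        )
    with open(path / "params.pkl", "rb") as fh:
        impl = pickle.load(fh)
    spec = ModelSpec(meta["family"], meta["hyperparams"], meta["seed"])
    return FittedModel(spec=spec, impl=impl, training_manifest=meta["manifest"])
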