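"""Reference predictors used to validate the trial-simulation framework.

These expose the same ``predict_batch(instances) -> (n, 20)`` surface as a
fitted model but are constructed analytically:

* :class:`OraclePredictor` returns the observed recovery exactly -- the
  perfect counterfactual, under which the synthetic-control group difference
  must be identically zero;
* :class:`NoisyOraclePredictor` adds independent Gaussian noise per motor
  coordinate (unbiased, optionally unclipped so that unbiasedness is exact),
  emulating an imperfect but calibration-free model;
* :class:`BiasedOraclePredictor` adds a constant shift, emulating a model
  with a systematic over-/underestimation;
* :class:`CarryForwardPredictor` returns the acute scores unchanged -- the
  no-recovery null every learned model must beat.

Noise is a deterministic function of (seed, patient id, assessment times),
so a predictor behaves like a frozen model: the same instance always gets
the same prediction.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np

from ..assessment import Instance

__all__ = [
    "OraclePredictor",
    "NoisyOraclePredictor",
    "BiasedOraclePredictor",
    "CarryForwardPredictor",
]


class OraclePredictor:
    """Predicts the observed late motor scores exactly."""

    def predict_batch(self, instances: Sequence[Instance]) -> np.ndarray:
        return np.stack([i.late.motor.reshape(-1).astype(float) for i in instances])


class CarryForwardPredictor:
    """No-recovery null: the late scores equal the early scores."""

    def predict_batch(self, instances: Sequence[Instance]) -> np.ndarray:
        return np.stack([i.early.motor.reshape(-1).astype(float) for i in instances])


def _instance_rng(seed: int, inst: Instance) -> np.random.Generator:
    key = f"{inst.patient_id}|{inst.early.dai}|{inst.late.dai}".encode()
    return np.random.default_rng([seed, zlib.crc32(key)])


class NoisyOraclePredictor:
    """Observed recovery plus independent N(0, sd) noise per coordinate.

    With ``clip=False`` (default) the prediction is exactly unbiased; with
    ``clip=True`` predictions respect the [0, 5] score range at the cost of
    a small bias at the boundaries.
    """

    def __init__(self, sd: float = 0.5, seed: int = 0, clip: bool = False):
        self.sd, self.seed, self.clip = float(sd), int(seed), bool(clip)

    def predict_batch(self, instances: Sequence[Instance]) -> np.ndarray:
        out = np.empty((len(instances), 20))
        for i, inst in enumerate(instances):
            rng = _instance_rng(self.seed, inst)
            pred = inst.late.motor.reshape(-1).astype(float) + rng.normal(0, self.sd, 20)
            out[i] = np.clip(pred, 0, 5) if self.clip else pred
        return out


class BiasedOraclePredictor:
    """Observed recovery plus a constant additive bias on every coordinate."""

    def __init__(self, bias: float):
        self.bias = float(bias)

    def predict_batch(self, instances: Sequence[Instance]) -> np.ndarray:
        return OraclePredictor().predict_batch(instances) + self.bias
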