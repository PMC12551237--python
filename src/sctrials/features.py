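"""Deterministic, schema-versioned encoding of an analysis pair.

The sequence block aligns, per side and key-muscle level, the early motor
score with the light-touch and pinprick scores of the corresponding
dermatome (rostro-caudal order).  The scalar block carries the covariates:
age, sex, assessment times, AIS one-hot, VAC, DAP and the NLI index.  Late
motor scores -- the prediction target -- are never encoded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assessment import Instance
from .levels import KEY_MUSCLE_LEVELS, LEVEL_LABELS, SIDES

__all__ = ["FeatureEncoding", "encode", "encode_batch", "target_batch",
           "SCHEMA_VERSION", "feature_names", "target_names"]

SCHEMA_VERSION = "fe-1"

_KEY_ANAT_ROW = np.array([LEVEL_LABELS.index(lev) for lev in KEY_MUSCLE_LEVELS])

#: sequence channels, in tensor order (channel, position)
SEQUENCE_CHANNELS = ("ms_left", "ms_right", "lt_left", "lt_right", "pp_left", "pp_right")
SCALAR_NAMES = ("age", "sex", "early_dai", "late_dai",
                "ais_A", "ais_B", "ais_C", "ais_D", "vac", "dap", "nli_index")

# normalization constants: keep every input roughly O(1)
_AGE_SCALE, _DAI_SCALE, _NLI_SCALE = 100.0, 100.0, float(len(LEVEL_LABELS) - 1)


@dataclass(frozen=True)
class FeatureEncoding:
    """Encoded instance: a (6, 10) sequence tensor plus 11 scalars."""

    sequence: np.ndarray
    scalars: np.ndarray
    schema_version: str = SCHEMA_VERSION

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate([self.sequence.ravel(), self.scalars])


def feature_names() -> list[str]:
    """Names of the flattened feature vector, sequence block first."""
    seq = [f"{ch}_{lev}" for ch in SEQUENCE_CHANNELS for lev in KEY_MUSCLE_LEVELS]
    return seq + list(SCALAR_NAMES)


def target_names() -> list[str]:
    """Names of the 20 predicted motor coordinates (level-major, L then R)."""
    return [f"ms_{lev}_{side}" for lev in KEY_MUSCLE_LEVELS for side in SIDES]


def encode_batch(instances: Sequence[Instance]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized encoding: returns (n, 6, 10) sequences and (n, 11) scalars."""
    n = len(instances)
    seq = np.empty((n, len(SEQUENCE_CHANNELS), len(KEY_MUSCLE_LEVELS)))
    scal = np.empty((n, len(SCALAR_NAMES)))
    for i, inst in enumerate(instances):
        e = inst.early
        seq[i, 0] = e.motor[:, 0] / 5.0
        seq[i, 1] = e.motor[:, 1] / 5.0
        seq[i, 2] = e.light_touch[_KEY_ANAT_ROW, 0] / 2.0
        seq[i, 3] = e.light_touch[_KEY_ANAT_ROW, 1] / 2.0
        seq[i, 4] = e.pinprick[_KEY_ANAT_ROW, 0] / 2.0
        seq[i, 5] = e.pinprick[_KEY_ANAT_ROW, 1] / 2.0
        ais_onehot = [1.0 if e.ais == g else 0.0 for g in "ABCD"]
        scal[i] = [
            inst.age / _AGE_SCALE,
            1.0 if inst.sex == "female" else 0.0,
            e.dai / _DAI_SCALE,
            inst.late.dai / _DAI_SCALE,
            *ais_onehot,
            1.0 if e.vac else 0.0,
            1.0 if e.dap else 0.0,
            e.nli.index / _NLI_SCALE,
        ]
    return seq, scal


def encode(instance: Instance) -> FeatureEncoding:
    """Encode one instance; raises naming the field if anything is missing."""
    try:
        seq, scal = encode_batch([instance])
    except AttributeError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot encode instance, missing field: {exc}") from exc
    return FeatureEncoding(sequence=seq[0], scalars=scal[0])


def target_batch(instances: Sequence[Instance]) -> np.ndarray:
    """Late motor scores as an (n, 20) array (level-major, left then right)."""
    return np.stack([inst.late.motor.reshape(-1).astype(float) for inst in instances])
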