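"""Tabular benchmark families: regularized linear, random forest, XGBoost.

These operate on the flattened encoding (sequence block + scalars) with one
multi-output regressor over the 20 motor coordinates.  The ridge penalty is
selected per output coordinate by internal cross-validation over the grid
1e-3 .. 1e3.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import RidgeCV
from xgboost import XGBRegressor

__all__ = ["RidgeFamily", "RandomForestFamily", "GradientBoostedFamily"]


def _flatten(X_seq: np.ndarray, X_scal: np.ndarray) -> np.ndarray:
    return np.concatenate([X_seq.reshape(X_seq.shape[0], -1), X_scal], axis=1)


class _TabularFamily:
    defaults: dict = {}

    def __init__(self, hyperparams: dict | None = None):
        hp = dict(self.defaults)
        hp.update(hyperparams or {})
        self.hp = hp
        self.model = None

    def fit(self, X_seq, X_scal, y, rng: np.random.Generator):
        self.model = self._build(int(rng.integers(2**31 - 1)))
        self.model.fit(_flatten(X_seq, X_scal), y)
        return self

    def predict(self, X_seq, X_scal) -> np.ndarray:
        return np.asarray(self.model.predict(_flatten(X_seq, X_scal)))


class RidgeFamily(_TabularFamily):
    defaults = {"alphas": tuple(np.logspace(-3, 3, 13))}

    def _build(self, seed):
        return RidgeCV(alphas=self.hp["alphas"], alpha_per_target=True)


class RandomForestFamily(_TabularFamily):
    defaults = {"n_estimators": 100, "min_samples_leaf": 2, "max_features": 0.5}

    def _build(self, seed):
        return RandomForestRegressor(
            n_estimators=self.hp["n_estimators"],
            min_samples_leaf=self.hp["min_samples_leaf"],
            max_features=self.hp["max_features"],
            random_state=seed, n_jobs=1,
        )


class GradientBoostedFamily(_TabularFamily):
    defaults = {"n_estimators": 200, "max_depth": 4, "learning_rate": 0.1}

    def _build(self, seed):
        return XGBRegressor(
            n_estimators=self.hp["n_estimators"],
            max_depth=self.hp["max_depth"],
            learning_rate=self.hp["learning_rate"],
            tree_method="hist", random_state=seed, n_jobs=1,
            verbosity=0,
        )
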