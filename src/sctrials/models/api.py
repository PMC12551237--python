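"""Model/Results front end for segmental recovery prediction.

Usage mirrors the fit/results idiom of statistical modelling packages::

    cohort = generate_cohort(default_emsci_config(n_patients=1000, seed=7))
    model = SegmentalRecoveryModel.from_cohort(cohort, family="conv_sequence")
    res = model.fit_cv(n_folds=5)
    print(res.summary())
    sim = res.simulate_trials(pool_instances)
    sizes = res.design_inputs(nisci_like_instances)

The Results object carries the fitted parameters, held-out errors when
cross-validation was requested, and exposes prediction, uncertainty bands,
importance analysis, trial simulation and design sizing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ..assessment import Instance
from .base import FittedModel, ModelSpec, Prediction, fit as _fit
from .base import perturb_predict as _perturb_predict
from .base import predict as _predict_one
from .base import predict_batch as _predict_batch

__all__ = ["SegmentalRecoveryModel", "SegmentalRecoveryResults"]


class SegmentalRecoveryModel:
    """Predicts recovery-phase segmental motor scores from acute ISNCSCI data.

    Parameters
    ----------
    instances : sequence of Instance
        Analysis pairs that already passed cohort inclusion.
    family : str
        One of the benchmark families (``linear_regularized``,
        ``random_forest``, ``gradient_boosted_trees``, ``conv_sequence``,
        ``seq2seq_attention``, ``graph_sequence``) or ``carry_forward``.
    """

    def __init__(
        self,
        instances: Sequence[Instance],
        family: str = "conv_sequence",
        hyperparams: dict | None = None,
        seed: int = 0,
    ):
        self.instances = list(instances)
        self.spec = ModelSpec(family, hyperparams or {}, seed)

    @classmethod
    def from_cohort(cls, cohort, family: str = "conv_sequence",
                    hyperparams: dict | None = None, seed: int = 0,
                    early_max_dai: int = 98, late_min_dai: int = 150):
        return cls(cohort.instances(early_max_dai, late_min_dai),
                   family=family, hyperparams=hyperparams, seed=seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: str = "wide", **kwargs):
        from ..io import records_from_dataframe
        from ..assessment import benchmark_inclusion

        return cls(benchmark_inclusion(records_from_dataframe(df, schema)), **kwargs)

    def fit(self) -> "SegmentalRecoveryResults":
        """Train on all instances."""
        return SegmentalRecoveryResults(self, _fit(self.spec, self.instances))

    def fit_cv(self, n_folds: int = 5) -> "SegmentalRecoveryResults":
        """Patient-level K-fold cross-validation plus a final full-data fit."""
        from ..evaluation import cross_validated_errors

        errors, preds = cross_validated_errors(
            self.instances, self.spec, n_folds=n_folds, seed=self.spec.seed
        )
        fitted = _fit(self.spec, self.instances)
        return SegmentalRecoveryResults(self, fitted, cv_errors=errors, cv_predictions=preds)


class SegmentalRecoveryResults:
    """Fitted recovery model with diagnostics and downstream analyses."""

    def __init__(self, model: SegmentalRecoveryModel, fitted: FittedModel,
                 cv_errors: pd.DataFrame | None = None,
                 cv_predictions: np.ndarray | None = None):
        self.model = model
        self.fitted = fitted
        self.cv_errors_ = cv_errors
        self.cv_predictions_ = cv_predictions

    # -- prediction ---------------------------------------------------------
    def predict(self, instances: Sequence[Instance] | None = None) -> np.ndarray:
        return _predict_batch(self.fitted, list(instances or self.model.instances))

    def predict_one(self, instance: Instance) -> Prediction:
        return _predict_one(self.fitted, instance)

    def perturb_predict(self, instance: Instance, n_reps: int = 30,
                        perturb_prob: float = 0.1, rng=None) -> Prediction:
        return _perturb_predict(self.fitted, instance, n_reps, perturb_prob, rng)

    # -- diagnostics --------------------------------------------------------
    @property
    def median_rmse_bl_nli_(self) -> float:
        if self.cv_errors_ is None:
            raise AttributeError("held-out errors require fit_cv()")
        return float(self.cv_errors_["rmse_bl_nli"].median())

    def error_summary(self, by_ais: bool = True) -> pd.DataFrame:
        from ..evaluation import summarize

        if self.cv_errors_ is None:
            raise AttributeError("held-out errors require fit_cv()")
        return summarize(self.cv_errors_, by_ais=by_ais)

    def time_profile(self, window: int = 7) -> pd.Series:
        from ..evaluation import time_profile

        if self.cv_errors_ is None:
            raise AttributeError("held-out errors require fit_cv()")
        return time_profile(self.cv_errors_, window=window)

    def importance(self, endpoint: tuple[str, str],
                   data: Sequence[Instance] | None = None,
                   n_repeats: int = 5, seed: int = 0) -> pd.DataFrame:
        from ..evaluation import importance

        return importance(self.fitted, list(data or self.model.instances),
                          endpoint, n_repeats=n_repeats, seed=seed)

    def summary(self) -> str:
        """Human-readable fit report."""
        spec = self.fitted.spec
        man = self.fitted.training_manifest
        lines = [
            "Segmental motor recovery model",
            "=" * 46,
            f"family:            {spec.family}",
            f"seed:              {spec.seed}",
            f"instances trained: {man['n_instances']} ({man['n_patients']} patients)",
        ]
        if self.fitted.loss_curve_:
            lines.append(
                f"training loss:     {self.fitted.loss_curve_[0]:.4f} -> "
                f"{self.fitted.loss_curve_[-1]:.4f} over {len(self.fitted.loss_curve_)} epochs"
            )
        if self.cv_errors_ is not None:
            n_folds = self.cv_errors_["fold"].nunique()
            lines += [
                f"cross-validation:  {n_folds}-fold, by patient",
                "",
                "Held-out RMSE below the NLI",
                "-" * 46,
                self.error_summary().pivot_table(
                    index="stratum", columns="statistic", values="value"
                ).loc[:, ["median", "p2.5", "p97.5", "n"]].round(3).to_string(),
            ]
        return "\n".join(lines)

    # -- downstream ---------------------------------------------------------
    def simulate_trials(self, pool: Sequence[Instance], tolerances=None,
                        max_early_dai: int = 40):
        """Trial simulator using this model as the synthetic-control source.

        The pool must be disjoint (by patient) from the training data; this
        is checked against the training manifest's patient set.
        """
        from ..simulation import MatchTolerances, TrialSimulation

        train_pids = {i.patient_id for i in self.model.instances}
        overlap = train_pids & {i.patient_id for i in pool}
        if overlap:
            raise ValueError(
                f"simulation pool shares {len(overlap)} patients with the "
                "training data; synthetic controls must come from a model "
                "trained on disjoint patients"
            )
        return TrialSimulation(
            pool, self.fitted,
            tolerances=tolerances or MatchTolerances(),
            max_early_dai=max_early_dai,
        )

    def design_inputs(self, instances: Sequence[Instance]):
        from ..power import estimate_design_inputs

        return estimate_design_inputs(list(instances), self.fitted)

    def bootstrap_design(self, instances: Sequence[Instance], params=None,
                         n_boot: int = 1000, seed: int = 0) -> dict:
        from ..power import DesignParams, bootstrap_design

        return bootstrap_design(list(instances), self.fitted,
                                params or DesignParams(), n_boot=n_boot, seed=seed)

    # -- plotting -----------------------------------------------------------
    def plot_patient(self, instance: Instance, ax=None):
        """Acute, observed and predicted motor score sequences for a patient."""
        import matplotlib.pyplot as plt

        from ..levels import KEY_MUSCLE_LEVELS

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 5))
        pred = self.perturb_predict(instance)
        y = np.arange(len(KEY_MUSCLE_LEVELS))
        mean_lr = lambda v: v.reshape(10, 2).mean(axis=1)  # noqa: E731
        ax.plot(mean_lr(instance.early.motor.reshape(-1).astype(float)), y,
                ls="--", color="0.5", label="acute")
        ax.plot(mean_lr(instance.late.motor.reshape(-1).astype(float)), y,
                color="k", label="observed recovery")
        ax.plot(mean_lr(pred.motor_pred), y, color="tab:orange", label="predicted")
        ax.fill_betweenx(y, mean_lr(pred.lower), mean_lr(pred.upper),
                         color="tab:orange", alpha=0.25, lw=0)
        ax.set_yticks(y, KEY_MUSCLE_LEVELS)
        ax.invert_yaxis()
        ax.set_xlabel("motor score (L/R mean)")
        ax.set_xlim(-0.2, 5.2)
        ax.legend(frameon=False, fontsize=8)
        return ax
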