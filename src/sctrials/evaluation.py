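"""Benchmark metrics and analyses.

The central metric is RMSE_bl.NLI: the root mean squared error between
predicted and observed segmental motor scores restricted to key muscles
strictly caudal to the initial neurological level of injury, which makes
errors comparable across patients with different lesion levels.  The module
also provides the signed residual companion (positive = overestimation),
percentile summaries overall and per AIS stratum, the rolling time profile
of performance against assessment time, patient-level cross-validation, and
a permutation-based feature-importance analysis with aggregation by
segmental distance from the endpoint myotome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assessment import Assessment, Instance
from .features import feature_names
from .levels import (
    KEY_MUSCLE_LEVELS,
    SIDES,
    as_level,
    myotomes_below_nli,
    segment_distance,
)
from .models.base import FittedModel, ModelSpec, fit, predict_batch

__all__ = [
    "InstanceError",
    "rmse_bl_nli",
    "mean_residual_bl_nli",
    "summarize",
    "time_profile",
    "cross_validated_errors",
    "patient_folds",
    "importance",
    "aggregate_by_distance",
]

_KEY_ROW = {lev: i for i, lev in enumerate(KEY_MUSCLE_LEVELS)}
_SIDE_COL = {side: j for j, side in enumerate(SIDES)}


def _below_nli_indices(nli) -> np.ndarray:
    """Flat indices (into the 20-vector) of key muscles strictly below nli."""
    coords = myotomes_below_nli(nli)
    return np.array([2 * _KEY_ROW[lev] + _SIDE_COL[side] for lev, side in coords])


def _as_vector(x) -> np.ndarray:
    if isinstance(x, Assessment):
        return x.motor.reshape(-1).astype(float)
    if hasattr(x, "motor_pred"):
        return np.asarray(x.motor_pred, float).reshape(-1)
    return np.asarray(x, float).reshape(-1)


def rmse_bl_nli(pred, obs, nli) -> float:
    """RMSE over key-muscle motor scores strictly caudal to the initial NLI."""
    idx = _below_nli_indices(nli)
    diff = _as_vector(pred)[idx] - _as_vector(obs)[idx]
    return float(np.sqrt(np.mean(diff ** 2)))


def mean_residual_bl_nli(pred, obs, nli) -> float:
    """Mean signed residual below the NLI; positive means overestimation."""
    idx = _below_nli_indices(nli)
    return float(np.mean(_as_vector(pred)[idx] - _as_vector(obs)[idx]))


@dataclass
class InstanceError:
    """Per-instance benchmark errors and stratification covariates."""

    rmse_bl_nli: float
    mean_residual_bl_nli: float
    early_dai: int
    ais: str

    def __post_init__(self) -> None:
        if self.rmse_bl_nli < 0:
            raise ValueError("rmse must be non-negative")


def _errors_frame(errors) -> pd.DataFrame:
    if isinstance(errors, pd.DataFrame):
        return errors
    return pd.DataFrame(
        {
            "rmse_bl_nli": [e.rmse_bl_nli for e in errors],
            "mean_residual_bl_nli": [e.mean_residual_bl_nli for e in errors],
            "early_dai": [e.early_dai for e in errors],
            "ais": [e.ais for e in errors],
        }
    )


def _stats(vals: np.ndarray) -> dict[str, float]:
    return {
        "median": float(np.median(vals)),
        "p2.5": float(np.percentile(vals, 2.5)),
        "p97.5": float(np.percentile(vals, 97.5)),
        "n": int(len(vals)),
    }


def summarize(errors, by_ais: bool = True) -> pd.DataFrame:
    """Tidy summary: median and (2.5, 97.5) percentiles of RMSE_bl.NLI and
    the median signed residual, overall and per AIS stratum.

    Percentiles use linear interpolation between order statistics.  Empty
    strata are absent from the output rather than reported as zero.
    """
    df = _errors_frame(errors)
    if df.empty:
        raise ValueError("no errors to summarize")
    rows = []

    def add(stratum: str, sub: pd.DataFrame) -> None:
        s = _stats(sub["rmse_bl_nli"].to_numpy())
        s["median_residual"] = float(np.median(sub["mean_residual_bl_nli"]))
        for stat, val in s.items():
            rows.append({"stratum": stratum, "statistic": stat, "value": val})

    add("all", df)
    if by_ais:
        for grade, sub in df.groupby("ais", sort=True):
            if len(sub):
                add(str(grade), sub)
    return pd.DataFrame(rows)


def time_profile(errors, window: int = 7) -> pd.Series:
    """Daily median RMSE_bl.NLI smoothed by a centered rolling mean.

    Medians are taken per day of initial assessment over the days that have
    data; the rolling mean (default 7 calendar days, centered, minimum one
    observed day) is then evaluated at those days.
    """
    df = _errors_frame(errors)
    daily = df.groupby("early_dai")["rmse_bl_nli"].median()
    full = daily.reindex(range(int(daily.index.min()), int(daily.index.max()) + 1))
    smooth = full.rolling(window, center=True, min_periods=1).mean()
    return smooth[daily.index]


# ---------------------------------------------------------------------------
# Cross-validated benchmark
# ---------------------------------------------------------------------------

def patient_folds(instances: Sequence[Instance], n_folds: int, rng) -> np.ndarray:
    """Fold assignment per instance with all instances of a patient in one
    fold (the cohorts count instances and patients separately, so leakage
    across folds through repeated patients must be prevented)."""
    pids = sorted({i.patient_id for i in instances})
    if len(pids) < n_folds:
        raise ValueError(f"need at least {n_folds} patients for {n_folds}-fold CV")
    order = rng.permutation(len(pids))
    fold_of_pid = {pids[j]: k % n_folds for k, j in enumerate(order)}
    return np.array([fold_of_pid[i.patient_id] for i in instances])


def cross_validated_errors(
    instances: Sequence[Instance],
    spec: ModelSpec,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Held-out errors under patient-level K-fold cross-validation.

    Returns the per-instance error table (with fold ids) and the (n, 20)
    matrix of held-out predictions aligned with ``instances``.
    """
    instances = list(instances)
    rng = np.random.default_rng(seed)
    folds = patient_folds(instances, n_folds, rng)
    preds = np.full((len(instances), 20), np.nan)
    for k in range(n_folds):
        train = [i for i, f in zip(instances, folds) if f != k]
        test_idx = np.flatnonzero(folds == k)
        if len(test_idx) == 0:
            continue
        model = fit(ModelSpec(spec.family, spec.hyperparams, seed=spec.seed + k), train)
        preds[test_idx] = predict_batch(model, [instances[j] for j in test_idx])
    rows = []
    for j, inst in enumerate(instances):
        rows.append(
            {
                "patient_id": inst.patient_id,
                "fold": int(folds[j]),
                "rmse_bl_nli": rmse_bl_nli(preds[j], inst.late, inst.early.nli),
                "mean_residual_bl_nli": mean_residual_bl_nli(preds[j], inst.late, inst.early.nli),
                "early_dai": inst.early.dai,
                "ais": inst.early.ais,
            }
        )
    return pd.DataFrame(rows), preds


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------

def importance(
    model: FittedModel,
    data: Sequence[Instance],
    endpoint: tuple[str, str],
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance for one endpoint motor coordinate.

    Each feature column is shuffled across the probe instances and the
    increase in mean squared prediction error at the endpoint coordinate is
    recorded (mean over ``n_repeats`` shuffles).  Rank 1 is the most
    important feature.  The backend is recorded in the table.
    """
    from .features import encode_batch

    lev, side = endpoint
    coord = 2 * _KEY_ROW[as_level(lev).label] + _SIDE_COL[side]
    X_seq, X_scal = encode_batch(list(data))
    y = np.stack([i.late.motor.reshape(-1)[coord] for i in data]).astype(float)
    base_pred = np.clip(model.impl.predict(X_seq, X_scal), 0, 5)[:, coord]
    base_mse = np.mean((base_pred - y) ** 2)
    rng = np.random.default_rng(seed)
    names = feature_names()
    n_seq = X_seq.shape[1] * X_seq.shape[2]
    scores = np.zeros(len(names))
    for f in range(len(names)):
        deltas = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(y))
            Xs, Xc = X_seq.copy(), X_scal.copy()
            if f < n_seq:
                ch, pos = divmod(f, X_seq.shape[2])
                Xs[:, ch, pos] = Xs[perm, ch, pos]
            else:
                Xc[:, f - n_seq] = Xc[perm, f - n_seq]
            pp = np.clip(model.impl.predict(Xs, Xc), 0, 5)[:, coord]
            deltas.append(np.mean((pp - y) ** 2) - base_mse)
        scores[f] = np.mean(deltas)
    table = pd.DataFrame({"feature": names, "score": scores})
    table["rank"] = table["score"].rank(ascending=False, method="first").astype(int)
    table["backend"] = "permutation"
    table.attrs["endpoint"] = (as_level(lev).label, side)
    return table.sort_values("rank").reset_index(drop=True)


def aggregate_by_distance(table: pd.DataFrame, endpoint: tuple[str, str] | None = None) -> pd.DataFrame:
    """Aggregate an importance table by proximity to the endpoint myotome.

    Sequence features are partitioned into cells of (signed segmental
    distance to the endpoint level, ipsilateral/contralateral, modality
    MS/LTS/PPS) and the mean rank per cell is reported; scalar covariates
    are kept as their own rows with kind ``covariate``.
    """
    if endpoint is None:
        endpoint = table.attrs.get("endpoint")
    if endpoint is None:
        raise ValueError("endpoint must be given or stored on the table")
    e_lev, e_side = as_level(endpoint[0]).label, endpoint[1]
    modality_map = {"ms": "MS", "lt": "LTS", "pp": "PPS"}
    rows = []
    for _, r in table.iterrows():
        parts = r["feature"].split("_")
        if len(parts) == 3 and parts[0] in modality_map:
            mod, side, lev = parts
            rows.append(
                {
                    "kind": "sequence",
                    "distance": segment_distance(e_lev, lev),
                    "laterality": "ipsilateral" if side == e_side else "contralateral",
                    "modality": modality_map[mod],
                    "rank": r["rank"],
                }
            )
        else:
            rows.append(
                {
                    "kind": "covariate", "distance": np.nan,
                    "laterality": "", "modality": r["feature"], "rank": r["rank"],
                }
            )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["kind", "distance", "laterality", "modality"], dropna=False)
        .agg(mean_rank=("rank", "mean"), n_features=("rank", "size"))
        .reset_index()
    )
    return agg.sort_values(["kind", "modality", "distance"]).reset_index(drop=True)
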