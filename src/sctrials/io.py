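"""Cohort file formats, run configuration and the pipeline driver.

The on-disk cohort format is a wide CSV: one row per (patient, assessment
day) with 20 motor, 56 light-touch and 56 pinprick columns plus VAC, DAP,
AIS, NLI, age and sex.  A long format (patient_id, dai, variable, value) is
accepted for interoperability.  Readers validate every score and report the
offending row; writers emit the wide form.

``run_pipeline`` executes the configured stages -- generate, include, train,
evaluate, simulate, power -- into an output directory whose manifest records
the configuration hash, seed and per-stage status, so every artifact is
traceable and a re-run with the same configuration reproduces the outputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .assessment import (
    Assessment,
    InvalidAssessmentError,
    PatientRecord,
    benchmark_inclusion,
    nisci_inclusion,
)
from .cohort import Cohort, CohortConfig, generate_cohort
from .levels import KEY_MUSCLE_LEVELS, LEVEL_LABELS, SIDES, as_level

logger = logging.getLogger(__name__)

__all__ = [
    "read_cohort", "write_cohort", "records_from_dataframe", "records_to_dataframe",
    "load_config", "save_config", "config_hash", "run_pipeline",
]

_MOTOR_COLS = [f"motor_{lev}_{side}" for lev in KEY_MUSCLE_LEVELS for side in SIDES]
_LT_COLS = [f"lt_{lev}_{side}" for lev in LEVEL_LABELS for side in SIDES]
_PP_COLS = [f"pp_{lev}_{side}" for lev in LEVEL_LABELS for side in SIDES]
_SCALAR_COLS = ["vac", "dap", "ais", "nli", "age", "sex"]
WIDE_COLUMNS = ["patient_id", "dai"] + _MOTOR_COLS + _LT_COLS + _PP_COLS + _SCALAR_COLS


def records_to_dataframe(records: Sequence[PatientRecord], schema: str = "wide") -> pd.DataFrame:
    """Serialize patient records to a wide or long table."""
    rows = []
    for rec in records:
        for a in rec.assessments:
            row: dict = {"patient_id": rec.patient_id, "dai": a.dai}
            m = a.motor.reshape(-1)
            row.update({c: int(v) for c, v in zip(_MOTOR_COLS, m)})
            row.update({c: int(v) for c, v in zip(_LT_COLS, a.light_touch.reshape(-1))})
            row.update({c: int(v) for c, v in zip(_PP_COLS, a.pinprick.reshape(-1))})
            row.update(
                vac=int(a.vac), dap=int(a.dap), ais=a.ais, nli=a.nli.label,
                age=rec.age_at_injury, sex=rec.sex,
            )
            rows.append(row)
    wide = pd.DataFrame(rows, columns=WIDE_COLUMNS)
    if schema == "wide":
        return wide
    if schema == "long":
        return wide.melt(
            id_vars=["patient_id", "dai"], var_name="variable", value_name="value"
        ).sort_values(["patient_id", "dai", "variable"]).reset_index(drop=True)
    raise ValueError(f"unknown schema {schema!r}")


def _sniff_schema(df: pd.DataFrame) -> str:
    return "long" if {"variable", "value"} <= set(df.columns) else "wide"


def records_from_dataframe(df: pd.DataFrame, schema: str | None = None) -> list[PatientRecord]:
    """Parse and validate a cohort table (wide or long) into records."""
    if schema is None:
        schema = _sniff_schema(df)
    if schema == "long":
        df = df.pivot_table(
            index=["patient_id", "dai"], columns="variable", values="value",
            aggfunc="first",
        ).reset_index()
    missing = [c for c in WIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing[:5]} ...")
    dupes = df.duplicated(subset=["patient_id", "dai"])
    if dupes.any():
        r = df[dupes].iloc[0]
        raise ValueError(
            f"duplicate assessment for patient {r['patient_id']!r} at dai {r['dai']}"
        )
    records: dict[str, PatientRecord] = {}
    kept = rejected = 0
    for rownum, row in df.iterrows():
        try:
            motor = np.array([float(row[c]) for c in _MOTOR_COLS]).reshape(10, 2)
            lt = np.array([float(row[c]) for c in _LT_COLS]).reshape(28, 2)
            pp = np.array([float(row[c]) for c in _PP_COLS]).reshape(28, 2)
            if not np.allclose(motor, np.rint(motor)):
                raise InvalidAssessmentError("non-integer motor score")
            a = Assessment(
                patient_id=str(row["patient_id"]), dai=int(row["dai"]),
                motor=np.rint(motor).astype(np.int16),
                light_touch=np.rint(lt).astype(np.int16),
                pinprick=np.rint(pp).astype(np.int16),
                vac=bool(int(float(row["vac"]))), dap=bool(int(float(row["dap"]))),
                ais=str(row["ais"]), nli=as_level(str(row["nli"])),
            )
        except (InvalidAssessmentError, ValueError) as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
        pid = str(row["patient_id"])
        if pid not in records:
            records[pid] = PatientRecord(
                patient_id=pid, age_at_injury=float(row["age"]),
                sex=str(row["sex"]), assessments=[],
            )
        records[pid].assessments.append(a)
        kept += 1
    for rec in records.values():
        rec.assessments.sort(key=lambda a: a.dai)
        dais = [a.dai for a in rec.assessments]
        if len(set(dais)) != len(dais):  # pragma: no cover - guarded above
            raise ValueError(f"duplicate assessment times for patient {rec.patient_id}")
    logger.info("parsed %d assessment rows into %d records (%d rejected)",
                kept, len(records), rejected)
    return list(records.values())


def read_cohort(path: str | Path, schema: str | None = None) -> list[PatientRecord]:
    return records_from_dataframe(
        pd.read_csv(path, float_precision="round_trip"), schema
    )


def write_cohort(records, path: str | Path, schema: str = "wide") -> Path:
    if isinstance(records, Cohort):
        records = records.records
    path = Path(path)
    # %.17g keeps float covariates (age) exact across the round trip
    records_to_dataframe(records, schema).to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the configured stages end to end.

    Stage failures are isolated: partial outputs are retained and the
    manifest marks the failed stage.  Training and simulation pools come
    from generator seeds derived from the run seed, so the synthetic-control
    model is never evaluated on its own training patients.
    """
    from .models.base import ModelSpec, fit, save_model
    from .evaluation import cross_validated_errors, summarize
    from .power import DesignParams, paired_n, two_sample_n, estimate_design_inputs
    from .simulation import TrialSimulation

    if not isinstance(config, dict):
        config = load_config(config)
    cfg_hash = config_hash(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "sctrials_run"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config_hash": cfg_hash, "seed": seed, "stages": {}, "artifacts": []}
    state: dict = {}

    def stage(name):
        return name in config

    def run_stage(name, fn):
        try:
            fn()
            manifest["stages"][name] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = f"failed: {exc}"

    def emit(name, obj):
        p = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(p, index=False)
        else:
            p.write_text(yaml.safe_dump(obj, sort_keys=True))
        manifest["artifacts"].append({"file": name, "config_hash": cfg_hash, "seed": seed})

    def do_generate():
        cc = dict(config.get("cohort", {}))
        cc.setdefault("seed", seed)
        cohort = generate_cohort(CohortConfig.from_dict(cc))
        state["cohort"] = cohort
        write_cohort(cohort, outdir / "cohort.csv")
        manifest["artifacts"].append(
            {"file": "cohort.csv", "config_hash": cfg_hash, "seed": cc["seed"]}
        )

    def do_include():
        inc = config.get("include", {}) or {}
        instances = benchmark_inclusion(
            state["cohort"].records,
            inc.get("early_max_dai", 98), inc.get("late_min_dai", 150),
        )
        state["instances"] = instances
        emit("inclusion.yaml", {
            "n_records": len(state["cohort"].records),
            "n_instances": len(instances),
        })

    def do_train():
        tr = config.get("train", {}) or {}
        spec = ModelSpec(tr.get("family", "conv_sequence"),
                         tr.get("hyperparams", {}) or {}, seed)
        model = fit(spec, state["instances"])
        state["model"] = model
        save_model(model, outdir / "model")
        manifest["artifacts"].append(
            {"file": "model/", "config_hash": cfg_hash, "seed": seed}
        )

    def do_evaluate():
        ev = config.get("evaluate", {}) or {}
        spec = state["model"].spec
        errors, _ = cross_validated_errors(
            state["instances"], spec, n_folds=ev.get("n_folds", 5), seed=seed
        )
        emit("cv_errors.csv", errors)
        emit("benchmark_summary.csv", summarize(errors))

    def do_simulate():
        sm = config.get("simulate", {}) or {}
        pool_cfg = dict(config.get("cohort", {}))
        pool_cfg["n_patients"] = sm.get("pool_patients", pool_cfg.get("n_patients", 1000))
        pool_cfg["seed"] = seed + 100_003  # disjoint generator stream
        pool = generate_cohort(CohortConfig.from_dict(pool_cfg)).instances()
        sim = TrialSimulation(pool, state["model"])
        summ = sim.repeat(
            n_trials=sm.get("n_trials", 500), size=sm.get("size", 200),
            seed=seed, plegia=sm.get("plegia", "both"),
        )
        state["pool"] = pool
        emit("sim_replicates.csv", summ.replicates)
        emit("sim_summary.csv", summ.summary())

    def do_power():
        pw = config.get("power", {}) or {}
        params = DesignParams(
            delta=pw.get("delta", 5.0), sd=pw.get("sd", 10.0),
            alpha=pw.get("alpha", 0.05), power=pw.get("power", 0.8),
        )
        report = {"alpha": params.alpha, "power": params.power, "delta": params.delta}
        if "pool" in state:
            subset = nisci_inclusion(state["pool"])
            if len(subset) >= 3:
                di = estimate_design_inputs(subset, state["model"])
                report["estimated_from_cohort"] = {
                    "n_instances": di.n,
                    "sd_two_sample": round(di.sd_two_sample, 3),
                    "sd_paired": round(di.sd_paired, 3),
                    "bias": round(di.bias, 3),
                    "single_arm_n": paired_n(DesignParams(
                        params.delta, di.sd_paired, params.alpha, params.power)),
                    "rct_total_n": 2 * two_sample_n(DesignParams(
                        params.delta, di.sd_two_sample, params.alpha, params.power)),
                }
        report["at_specified_sd"] = {
            "sd": params.sd,
            "single_arm_n": paired_n(params),
            "rct_total_n": 2 * two_sample_n(params),
        }
        emit("power.yaml", report)

    order = [
        ("generate", do_generate), ("include", do_include), ("train", do_train),
        ("evaluate", do_evaluate), ("simulate", do_simulate), ("power", do_power),
    ]
    for name, fn in order:
        if stage(name) or name in ("generate", "include"):
            run_stage(name, fn)
            if manifest["stages"][name] != "ok" and name in ("generate", "include", "train"):
                break  # later stages depend on these
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return outdir
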