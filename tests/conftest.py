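"""Shared fixtures: hand-built assessments and small generated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from sctrials.assessment import Assessment, PatientRecord
from sctrials.cohort import default_emsci_config, generate_cohort
from sctrials.levels import KEY_MUSCLE_LEVELS, LEVEL_LABELS, SIDES, as_level

_KEY_ROW = {lev: i for i, lev in enumerate(KEY_MUSCLE_LEVELS)}
_SIDE_COL = {s: j for j, s in enumerate(SIDES)}


def make_assessment(
    pid: str = "P1",
    dai: int = 14,
    ais: str = "B",
    nli: str = "C6",
    motor: dict | None = None,
    vac: bool = False,
    dap: bool = True,
    caudal_motor: int = 0,
    caudal_sensory: int = 0,
) -> Assessment:
    """Plausible assessment: full scores rostral to the NLI, ``caudal_*``
    below, with per-coordinate ``motor`` overrides."""
    nli_idx = as_level(nli).index
    m = np.zeros((10, 2), dtype=np.int16)
    for lev, row in _KEY_ROW.items():
        m[row, :] = 5 if as_level(lev).index <= nli_idx else caudal_motor
    for (lev, side), v in (motor or {}).items():
        m[_KEY_ROW[lev], _SIDE_COL[side]] = v
    sens = np.zeros((28, 2), dtype=np.int16)
    for i, lev in enumerate(LEVEL_LABELS):
        sens[i, :] = 2 if as_level(lev).index <= nli_idx else caudal_sensory
    return Assessment(
        patient_id=pid, dai=dai, motor=m, light_touch=sens.copy(),
        pinprick=sens.copy(), vac=vac, dap=dap, ais=ais, nli=as_level(nli),
    )


def cervical_motor(uems_target: int) -> dict:
    """Overrides putting ``uems_target`` points onto the C5-T1 key muscles."""
    motor = {}
    remaining = uems_target
    for lev in ("C5", "C6", "C7", "C8", "T1"):
        for side in SIDES:
            v = min(5, remaining)
            motor[(lev, side)] = v
            remaining -= v
    assert remaining == 0
    return motor


def make_record(pid="P1", age=45.0, sex="female", assessments=()) -> PatientRecord:
    return PatientRecord(
        patient_id=pid, age_at_injury=age, sex=sex, assessments=list(assessments)
    )


def make_pair(pid="P1", ais="B", nli="C6", early_dai=14, late_dai=180, **kw):
    """A record with one qualifying (early, late) assessment pair."""
    early = make_assessment(pid, early_dai, ais, nli, **kw)
    late = make_assessment(pid, late_dai, ais, nli, **kw)
    return make_record(pid=pid, assessments=[early, late])


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(default_emsci_config(n_patients=150, seed=7))


@pytest.fixture(scope="session")
def small_instances(small_cohort):
    return small_cohort.instances()
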