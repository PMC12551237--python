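"""ISNCSCI assessments, patient records, derived scores and cohort filters.

Scores are stored as small integer arrays indexed by the coordinate order of
:mod:`sctrials.levels` (level-major, left column then right column), which
keeps cohorts of tens of thousands of patients cheap.  Mapping-style access
and construction from ``{(level, side): value}`` dictionaries are provided
for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .levels import (
    KEY_MUSCLE_LEVELS,
    LEMS_LEVELS,
    LEVEL_LABELS,
    SIDES,
    UEMS_LEVELS,
    SpinalLevel,
    as_level,
)

__all__ = [
    "Assessment",
    "PatientRecord",
    "Instance",
    "InvalidAssessmentError",
    "uems",
    "lems",
    "deterioration_flag",
    "benchmark_inclusion",
    "nisci_inclusion",
]

AIS_GRADES = ("A", "B", "C", "D", "E")

_KEY_ROW = {lev: i for i, lev in enumerate(KEY_MUSCLE_LEVELS)}
_LEVEL_ROW = {lev: i for i, lev in enumerate(LEVEL_LABELS)}
_SIDE_COL = {side: j for j, side in enumerate(SIDES)}
_UEMS_ROWS = np.array([_KEY_ROW[lev] for lev in UEMS_LEVELS])
_LEMS_ROWS = np.array([_KEY_ROW[lev] for lev in LEMS_LEVELS])


class InvalidAssessmentError(ValueError):
    """An assessment violates the ISNCSCI score contract."""


def _coerce_scores(
    values: "np.ndarray | Mapping",
    levels: Sequence[str],
    low: int,
    high: int,
    what: str,
) -> np.ndarray:
    """Validate and densify a score block to an (n_levels, 2) int array."""
    n = len(levels)
    if isinstance(values, Mapping):
        arr = np.full((n, 2), -1, dtype=np.int16)
        row = _KEY_ROW if n == len(KEY_MUSCLE_LEVELS) else _LEVEL_ROW
        for (lev, side), v in values.items():
            arr[row[as_level(lev).label if lev not in row else lev], _SIDE_COL[side]] = v
    else:
        arr = np.asarray(values, dtype=np.int16)
        if arr.shape != (n, 2):
            raise InvalidAssessmentError(
                f"{what} block must have shape ({n}, 2), got {arr.shape}"
            )
        arr = arr.copy()
    missing = arr < 0
    if missing.any():
        i, j = np.argwhere(missing)[0]
        raise InvalidAssessmentError(
            f"missing {what} entry at ({levels[i]}, {SIDES[j]})"
        )
    if (arr > high).any() or (arr < low).any():
        bad = arr[(arr > high) | (arr < low)][0]
        raise InvalidAssessmentError(
            f"{what} score {bad} outside [{low}, {high}]"
        )
    return arr


@dataclass
class Assessment:
    """A single ISNCSCI examination at one time point.

    ``motor`` holds the 20 key-muscle scores (0-5) as a (10, 2) array over
    (key level, side); ``light_touch`` and ``pinprick`` the 56 dermatome
    scores (0-2) each as (28, 2) arrays.  AIS grade and NLI are consumed as
    given -- this package never re-derives the ISNCSCI classification.
    """

    patient_id: str
    dai: int
    motor: np.ndarray
    light_touch: np.ndarray
    pinprick: np.ndarray
    vac: bool
    dap: bool
    ais: str
    nli: SpinalLevel

    def __post_init__(self) -> None:
        if self.dai < 0:
            raise InvalidAssessmentError(f"dai must be non-negative, got {self.dai}")
        self.dai = int(self.dai)
        self.motor = _coerce_scores(self.motor, KEY_MUSCLE_LEVELS, 0, 5, "motor")
        self.light_touch = _coerce_scores(self.light_touch, LEVEL_LABELS, 0, 2, "light touch")
        self.pinprick = _coerce_scores(self.pinprick, LEVEL_LABELS, 0, 2, "pinprick")
        self.vac = bool(self.vac)
        self.dap = bool(self.dap)
        if self.ais not in AIS_GRADES:
            raise InvalidAssessmentError(f"AIS grade must be one of {AIS_GRADES}, got {self.ais!r}")
        self.nli = as_level(self.nli)

    # -- mapping-style access ------------------------------------------------
    def motor_score(self, level: str, side: str) -> int:
        return int(self.motor[_KEY_ROW[as_level(level).label], _SIDE_COL[side]])

    def motor_dict(self) -> dict[tuple[str, str], int]:
        return {
            (lev, side): int(self.motor[i, j])
            for i, lev in enumerate(KEY_MUSCLE_LEVELS)
            for j, side in enumerate(SIDES)
        }

    def replace_motor(self, motor: np.ndarray) -> "Assessment":
        """Copy of this assessment with a different motor block."""
        return Assessment(
            patient_id=self.patient_id, dai=self.dai, motor=motor,
            light_touch=self.light_touch, pinprick=self.pinprick,
            vac=self.vac, dap=self.dap, ais=self.ais, nli=self.nli,
        )


@dataclass
class PatientRecord:
    """Demographics plus the ordered series of ISNCSCI assessments."""

    patient_id: str
    age_at_injury: float
    sex: str
    assessments: list[Assessment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_at_injury <= 0:
            raise ValueError(f"age must be positive, got {self.age_at_injury}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        dais = [a.dai for a in self.assessments]
        if any(b <= a for a, b in zip(dais, dais[1:])):
            raise ValueError(
                f"assessments of patient {self.patient_id} must be strictly "
                f"increasing in dai, got {dais}"
            )


@dataclass
class Instance:
    """An (early assessment, late assessment, covariates) analysis pair."""

    early: Assessment
    late: Assessment
    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.early.patient_id != self.late.patient_id:
            raise ValueError("early and late assessments must belong to one patient")
        if not self.early.dai < self.late.dai:
            raise ValueError("early assessment must precede the late assessment")

    @property
    def patient_id(self) -> str:
        return self.early.patient_id


# ---------------------------------------------------------------------------
# Derived scores
# ---------------------------------------------------------------------------

def uems(a: Assessment) -> int:
    """Upper extremity motor score: sum of C5-T1 key muscles, both sides (0-50)."""
    return int(a.motor[_UEMS_ROWS].sum())


def lems(a: Assessment) -> int:
    """Lower extremity motor score: sum of L2-S1 key muscles, both sides (0-50)."""
    return int(a.motor[_LEMS_ROWS].sum())


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def deterioration_flag(early: Assessment, late: Assessment) -> bool:
    """True iff any key muscle lost two or more points between assessments.

    Patients showing such deterioration are excluded from the cohorts:
    typical recovery is non-decreasing, and drops of >= 2 points indicate
    unrecorded complications that no natural-course model should absorb.
    """
    return bool(((late.motor.astype(int) - early.motor.astype(int)) <= -2).any())


def benchmark_inclusion(
    records: "Sequence[PatientRecord]",
    early_max_dai: int = 98,
    late_min_dai: int = 150,
) -> list[Instance]:
    """Apply the model-benchmark cohort rules and enumerate analysis pairs.

    A patient contributes one instance per (early, late) assessment pair with
    ``early.dai <= early_max_dai`` and ``late.dai >= late_min_dai``; patients
    with AIS E, an NLI at or below S1, or any >= 2-point motor deterioration
    within a pair contribute nothing for that pair.  Patients with several
    qualifying early assessments enter as multiple instances.
    """
    if not early_max_dai < late_min_dai:
        raise ValueError("early_max_dai must be smaller than late_min_dai")
    s1_index = as_level("S1").index
    out: list[Instance] = []
    for rec in records:
        earlies = [a for a in rec.assessments if a.dai <= early_max_dai]
        lates = [a for a in rec.assessments if a.dai >= late_min_dai]
        for e in earlies:
            if e.ais not in ("A", "B", "C", "D"):
                continue
            if e.nli.index >= s1_index:
                continue
            for l in lates:
                if deterioration_flag(e, l):
                    continue
                out.append(Instance(early=e, late=l, age=rec.age_at_injury, sex=rec.sex))
    return out


def nisci_inclusion(
    instances: "Sequence[Instance]",
    baseline_max_dai: int = 28,
    followup_dai: int = 168,
    followup_window: int = 7,
    max_baseline_uems: int = 29,
) -> list[Instance]:
    """Filter instances to the NISCI trial's eligibility.

    Cervical injury (NLI C2-C8), baseline no later than 28 days after
    injury, follow-up at 168 +/- 7 days, and a baseline UEMS strictly below
    29 points (patients near the 50-point ceiling have no measurable upper
    extremity recovery left).
    """
    c8_index = as_level("C8").index
    lo, hi = followup_dai - followup_window, followup_dai + followup_window
    return [
        inst
        for inst in instances
        if inst.early.nli.index <= c8_index
        and inst.early.dai <= baseline_max_dai
        and lo <= inst.late.dai <= hi
        and uems(inst.early) < max_baseline_uems
    ]
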