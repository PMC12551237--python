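"""ISNCSCI spinal-level coordinate system.

The International Standards for Neurological Classification of Spinal Cord
Injury (ISNCSCI) examine 28 dermatome levels per side (C2 down to S4-5) and
10 key-muscle myotome levels per side (C5-T1 for the upper extremities,
L2-S1 for the lower extremities).  Everything in this package that is
"rostral"/"caudal" or "within N segments" is arithmetic on the rostro-caudal
index defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "LEVEL_LABELS",
    "KEY_MUSCLE_LEVELS",
    "UEMS_LEVELS",
    "LEMS_LEVELS",
    "SIDES",
    "SpinalLevel",
    "segment_distance",
    "myotomes_below_nli",
    "ExcludedPatientError",
]

#: The 28 ISNCSCI levels in rostro-caudal order.
LEVEL_LABELS: tuple[str, ...] = (
    "C2", "C3", "C4", "C5", "C6", "C7", "C8",
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
    "S1", "S2", "S3", "S4-5",
)

#: Key-muscle (myotome) levels carrying a 0-5 motor score, rostro-caudal.
KEY_MUSCLE_LEVELS: tuple[str, ...] = (
    "C5", "C6", "C7", "C8", "T1", "L2", "L3", "L4", "L5", "S1",
)

#: Upper / lower extremity motor score constituents (each 5 levels x 2 sides).
UEMS_LEVELS: tuple[str, ...] = ("C5", "C6", "C7", "C8", "T1")
LEMS_LEVELS: tuple[str, ...] = ("L2", "L3", "L4", "L5", "S1")

SIDES: tuple[str, str] = ("left", "right")

_INDEX_OF: dict[str, int] = {lab: i for i, lab in enumerate(LEVEL_LABELS)}


class ExcludedPatientError(ValueError):
    """Raised when a cohort rule excludes the patient (e.g. NLI at/below S1)."""


@dataclass(frozen=True, order=True)
class SpinalLevel:
    """One of the 28 ISNCSCI levels; ordering follows anatomy (rostral first).

    Parameters
    ----------
    index : int
        Position in rostro-caudal order, 0 (C2) to 27 (S4-5).
    """

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < len(LEVEL_LABELS):
            raise ValueError(f"spinal level index out of range: {self.index}")

    @property
    def label(self) -> str:
        return LEVEL_LABELS[self.index]

    @classmethod
    def from_label(cls, label: str) -> "SpinalLevel":
        try:
            return cls(_INDEX_OF[str(label).upper().replace("S45", "S4-5")])
        except KeyError:
            raise ValueError(f"unknown spinal level label: {label!r}") from None

    @property
    def region(self) -> str:
        """Anatomical region: cervical, thoracic, lumbar or sacral."""
        if self.index <= _INDEX_OF["C8"]:
            return "cervical"
        if self.index <= _INDEX_OF["T12"]:
            return "thoracic"
        if self.index <= _INDEX_OF["L5"]:
            return "lumbar"
        return "sacral"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SpinalLevel({self.label})"


def as_level(level: "SpinalLevel | str | int") -> SpinalLevel:
    """Coerce a label, index or SpinalLevel to a SpinalLevel."""
    if isinstance(level, SpinalLevel):
        return level
    if isinstance(level, int):
        return SpinalLevel(level)
    return SpinalLevel.from_label(level)


def segment_distance(a: "SpinalLevel | str", b: "SpinalLevel | str") -> int:
    """Signed number of segments from ``a`` to ``b`` (positive = b caudal)."""
    return as_level(b).index - as_level(a).index


def myotomes_below_nli(nli: "SpinalLevel | str") -> list[tuple[str, str]]:
    """Key-muscle coordinates strictly caudal to the neurological level.

    Both sides are included, in rostro-caudal order with left before right.
    Patients with an NLI at or below S1 have no key muscle below the level
    under the cohort rules and are excluded.
    """
    nli = as_level(nli)
    if nli.index >= _INDEX_OF["S1"]:
        raise ExcludedPatientError(
            f"NLI {nli.label} is at or below S1; patient excluded from analysis"
        )
    coords = [
        (lev, side)
        for lev in KEY_MUSCLE_LEVELS
        if _INDEX_OF[lev] > nli.index
        for side in SIDES
    ]
    return coords


def iter_motor_coordinates() -> Iterator[tuple[str, str]]:
    """All 20 key-muscle coordinates, level-major, left then right."""
    for lev in KEY_MUSCLE_LEVELS:
        for side in SIDES:
            yield (lev, side)


def iter_sensory_coordinates() -> Iterator[tuple[str, str]]:
    """All 56 dermatome coordinates, level-major, left then right."""
    for lev in LEVEL_LABELS:
        for side in SIDES:
            yield (lev, side)
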