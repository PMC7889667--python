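"""Clavien-Dindo grades, grade weights, and the comprehensive complication index.

The comprehensive complication index (CCI) summarises *all* graded
complications of one surgical course on a 0-100 scale:

    CCI = sqrt(wC1 + wC2 + ... + wCx) / 2

where each wC is the weight of one occurred complication, looked up from its
Clavien-Dindo grade. A course with no complications scores 0; a course
containing a grade V complication (death) scores 100. Repeated events of the
same kind each contribute their weight again.

This module also encodes the liver-transplant-specific conventions that map
clinical events (retransplantation, primary non-function, early allograft
dysfunction, ...) onto Clavien-Dindo grades before scoring.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


@enum.unique
class ClavienDindoGrade(enum.IntEnum):
    """Clavien-Dindo complication grade; the integer value encodes severity order."""

    I = 1
    II = 2
    IIIa = 3
    IIIb = 4
    IVa = 5
    IVb = 6
    V = 7

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name

    @classmethod
    def from_string(cls, text: str) -> "ClavienDindoGrade":
        """Parse a grade label such as ``"IIIa"``; raises ValueError on anything else."""
        try:
            return cls[text.strip()]
        except KeyError:
            valid = ", ".join(g.name for g in cls)
            raise ValueError(f"unknown Clavien-Dindo grade {text!r} (expected one of {valid})") from None


#: Grade weights wC inside the square root.  These reproduce the published
#: per-grade single-event index values (8.7, 20.9, 26.2, 33.7, 42.4, 46.2, 100)
#: at one-decimal rounding, with the grade V value forced to 100 (death).
CANONICAL_WEIGHTS: Mapping[ClavienDindoGrade, float] = {
    ClavienDindoGrade.I: 300.0,
    ClavienDindoGrade.II: 1750.0,
    ClavienDindoGrade.IIIa: 2750.0,
    ClavienDindoGrade.IIIb: 4550.0,
    ClavienDindoGrade.IVa: 7200.0,
    ClavienDindoGrade.IVb: 8550.0,
    ClavienDindoGrade.V: 39940.0,
}

#: Index value of a course containing exactly that single complication.
SINGLE_EVENT_VALUES: Mapping[ClavienDindoGrade, float] = {
    ClavienDindoGrade.I: 8.7,
    ClavienDindoGrade.II: 20.9,
    ClavienDindoGrade.IIIa: 26.2,
    ClavienDindoGrade.IIIb: 33.7,
    ClavienDindoGrade.IVa: 42.4,
    ClavienDindoGrade.IVb: 46.2,
    ClavienDindoGrade.V: 100.0,
}


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (clinical-report convention, unlike banker's rounding)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class GradeWeightTable:
    """Mapping from Clavien-Dindo grade to the weight wC used inside the square root.

    The default table is :data:`CANONICAL_WEIGHTS`.  An alternative inversion
    ``wC = (2 * single_event_value)**2`` can be swapped in via
    :meth:`from_single_event_values`.
    """

    weights: Mapping[ClavienDindoGrade, float] = field(default_factory=lambda: dict(CANONICAL_WEIGHTS))

    def __post_init__(self) -> None:
        missing = [g.name for g in ClavienDindoGrade if g not in self.weights]
        if missing:
            raise ValueError(f"weight table is missing grades: {missing}")
        ordered = [self.weights[g] for g in ClavienDindoGrade]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("grade weights must strictly increase with grade")

    def weight(self, grade: ClavienDindoGrade) -> float:
        return self.weights[grade]

    def single_event_value(self, grade: ClavienDindoGrade) -> float:
        """Index value of a one-event course of ``grade`` (grade V forced to 100)."""
        if grade is ClavienDindoGrade.V:
            return 100.0
        return round_half_away(math.sqrt(self.weights[grade]) / 2.0, 1)

    @classmethod
    def from_single_event_values(
        cls, values: Mapping[ClavienDindoGrade, float] = SINGLE_EVENT_VALUES
    ) -> "GradeWeightTable":
        """Invert printed per-grade values into weights via wC = (2 * value)^2."""
        return cls({g: (2.0 * values[g]) ** 2 for g in ClavienDindoGrade})


@dataclass(frozen=True)
class ComplicationEvent:
    """One graded adverse event in a patient's post-transplant course.

    ``label`` is free text (e.g. ``"EAD"``, ``"reoperation for bleeding"``);
    ``day`` is days after transplant, if recorded.  Duplicate
    (patient, grade, label) events are allowed and each one counts.
    """

    patient_id: str
    grade: ClavienDindoGrade
    label: Optional[str] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.grade, ClavienDindoGrade):
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.day is not None and self.day < 0:
            raise ValueError(f"event day must be >= 0, got {self.day}")


@dataclass(frozen=True)
class CCIScore:
    """CCI of one patient: ``value`` in [0, 100]; zero iff the course had no events."""

    patient_id: str
    value: float
    n_events: int

    @property
    def display(self) -> float:
        """Value rounded half-away-from-zero to one decimal, as reported clinically."""
        return round_half_away(self.value, 1)


def compute_cci(
    events: Sequence[ComplicationEvent],
    weights: GradeWeightTable | None = None,
    *,
    day_cutoff: Optional[int] = None,
) -> CCIScore:
    """Compute the comprehensive complication index for one patient's course.

    Parameters
    ----------
    events
        All graded complications of a single patient. May be empty (CCI 0).
    weights
        Grade weight table; defaults to the canonical one.
    day_cutoff
        If given, events with a recorded day greater than ``day_cutoff`` are
        ignored — used to restrict scoring to the first post-transplant
        hospitalization (events up to the discharge day). Events without a
        recorded day are always kept.

    Returns
    -------
    CCIScore
        Unrounded internally; use :attr:`CCIScore.display` for the one-decimal
        reported value. Any grade V event forces the value to exactly 100, and
        large sums are capped at 100.

    Raises
    ------
    ValueError
        If the events carry more than one patient id.
    """
    weights = weights or GradeWeightTable()
    ids = {e.patient_id for e in events}
    if len(ids) > 1:
        a, b, *_ = sorted(ids)
        raise ValueError(f"events mix patient ids ({a!r} and {b!r}); score one patient at a time")
    patient_id = next(iter(ids)) if ids else ""

    if day_cutoff is not None:
        events = [e for e in events if e.day is None or e.day <= day_cutoff]

    if not events:
        return CCIScore(patient_id=patient_id, value=0.0, n_events=0)
    if any(e.grade is ClavienDindoGrade.V for e in events):
        return CCIScore(patient_id=patient_id, value=100.0, n_events=len(events))
    total = sum(weights.weight(e.grade) for e in events)
    value = min(100.0, math.sqrt(total) / 2.0)
    return CCIScore(patient_id=patient_id, value=value, n_events=len(events))


class ClinicalEvent(str, enum.Enum):
    """Liver-transplant clinical events with a conventional Clavien-Dindo translation."""

    EAD = "EAD"
    PNF = "PNF"
    MOF = "MOF"
    RETRANSPLANTATION = "retransplantation"
    MILD_RENAL_DYSFUNCTION = "mild_renal_dysfunction"
    RRT = "RRT"
    MYELOTOXICITY = "myelotoxicity"
    DEATH = "death"


# LT-specific grading conventions: early allograft dysfunction counts as a
# grade II complication; primary non-function and renal replacement therapy as
# IVa; multiorgan failure as IVb; mild renal dysfunction (creatinine > 1.5
# mg/dL without dialysis) and myelotoxicity as grade I; retransplantation in
# the first hospitalization as liver failure (IVa) plus reoperation (IIIb).
_CLINICAL_EVENT_GRADES: Mapping[ClinicalEvent, tuple[ClavienDindoGrade, ...]] = {
    ClinicalEvent.EAD: (ClavienDindoGrade.II,),
    ClinicalEvent.PNF: (ClavienDindoGrade.IVa,),
    ClinicalEvent.MOF: (ClavienDindoGrade.IVb,),
    ClinicalEvent.RETRANSPLANTATION: (ClavienDindoGrade.IVa, ClavienDindoGrade.IIIb),
    ClinicalEvent.MILD_RENAL_DYSFUNCTION: (ClavienDindoGrade.I,),
    ClinicalEvent.RRT: (ClavienDindoGrade.IVa,),
    ClinicalEvent.MYELOTOXICITY: (ClavienDindoGrade.I,),
    ClinicalEvent.DEATH: (ClavienDindoGrade.V,),
}


def grade_clinical_event(event_kind: ClinicalEvent | str) -> list[ClavienDindoGrade]:
    """Translate a named clinical event into the Clavien-Dindo grades it contributes.

    Retransplantation expands to two complications (IVa liver failure plus
    IIIb reoperation); every other event maps to a single grade.
    """
    try:
        kind = ClinicalEvent(event_kind)
    except ValueError:
        valid = ", ".join(e.value for e in ClinicalEvent)
        raise ValueError(f"unknown clinical event kind {event_kind!r} (expected one of {valid})") from None
    return list(_CLINICAL_EVENT_GRADES[kind])


def highest_grade(events: Iterable[ComplicationEvent]) -> Optional[ClavienDindoGrade]:
    """Highest Clavien-Dindo grade of a course, or None for an uncomplicated one."""
    grades = [e.grade for e in events]
    return max(grades) if grades else None
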