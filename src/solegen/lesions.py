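"""Claw-level lesion data model and binary trait derivation.

Sole hemorrhage and sole ulcers ("sole lesions") are claw-horn lesions of
the bovine foot. Each animal is assessed at four timepoints in a production
cycle (T1 pre-calving, T2 calving, T3 early lactation, T4 late lactation),
with up to 8 claws graded per assessment. Two binary genetic traits are
derived:

* **SL-Susceptibility** — 1 if the animal had a sole lesion (severe sole
  hemorrhage or a sole ulcer) on any claw at any assessment; 0 only for
  animals unaffected at every claw in a complete four-timepoint record set;
  otherwise unclassified.
* **SL-Recovery** — defined only for animals affected at T3 with complete
  8-claw records at both T3 and T4; 1 if every claw affected at T3 is no
  longer affected at T4, 0 if at least one affected claw remains affected
  ("chronic").

Mild sole hemorrhage is considered unaffected throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LesionGrade",
    "CohortRecords",
    "TraitRecord",
    "Prevalence",
    "TIMEPOINTS",
    "CLAW_POSITIONS",
    "is_affected",
    "claw_outcome",
    "classify_susceptibility",
    "classify_recovery",
    "derive_traits",
    "prevalence",
]

TIMEPOINTS = ("T1", "T2", "T3", "T4")

#: the 8 claw positions: (limb, side, claw)
CLAW_POSITIONS = tuple(
    (limb, side, claw)
    for limb in ("fore", "hind")
    for side in ("left", "right")
    for claw in ("medial", "lateral")
)

LAME_SCORES = frozenset({2, 3})


class LesionGrade(enum.IntEnum):
    """Ordinal severity of a sole lesion on one claw.

    The order is NONE < MILD_SH < SEVERE_SH < ULCER; a claw is *affected*
    iff its grade is at least SEVERE_SH (mild hemorrhage counts as
    unaffected).
    """

    NONE = 0
    MILD_SH = 1
    SEVERE_SH = 2
    ULCER = 3


#: grades >= this constant count as affected
AFFECTED_THRESHOLD = LesionGrade.SEVERE_SH


class MissingGradeError(ValueError):
    """A lesion grade required by a classification rule is missing."""


@dataclass
class TraitRecord:
    """Per-animal outcome of one binary trait derivation.

    ``value`` is 1/0 when the classification rules are satisfiable and
    ``None`` when the animal is unclassified. ``interval_days`` is the
    T3→T4 interval, attached for SL-Recovery only.
    """

    animal: int
    trait: str
    value: int | None
    interval_days: float | None = None


@dataclass
class Prevalence:
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float:
        if self.denominator == 0:
            raise ZeroDivisionError("empty prevalence denominator")
        return self.numerator / self.denominator


@dataclass
class CohortRecords:
    """Longitudinal claw-level lesion records plus per-assessment metadata.

    ``claws`` columns: animal, timepoint, limb, side, claw, grade
    (integer LesionGrade code; NaN = missing).
    ``assessments`` columns: animal, timepoint, days_from_calving,
    mobility (0-3 or NaN), herd, parity (1/2/3), hys.
    """

    claws: pd.DataFrame
    assessments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"animal", "timepoint", "limb", "side", "claw", "grade"}
        missing = required - set(self.claws.columns)
        if missing:
            raise ValueError(f"claw table missing columns: {sorted(missing)}")
        dup = self.claws.duplicated(["animal", "timepoint", "limb", "side", "claw"])
        if dup.any():
            raise ValueError("duplicate claw observation for an (animal, timepoint, position)")

    @property
    def animals(self) -> np.ndarray:
        return np.unique(self.claws["animal"].to_numpy())


def is_affected(grade: LesionGrade | int | float) -> bool:
    """True iff the grade indicates a sole lesion (severe SH or ulcer)."""
    if grade is None or (isinstance(grade, float) and np.isnan(grade)):
        raise MissingGradeError("cannot determine affected status from a missing grade")
    return int(grade) >= AFFECTED_THRESHOLD


def claw_outcome(grade_t3, grade_t4) -> str:
    """Outcome of one claw affected at T3: ``"recovered"`` or ``"chronic"``.

    A claw has recovered iff its T4 grade is below SEVERE_SH — an ulcer
    followed by severe hemorrhage on the same claw is still chronic.
    """
    if not is_affected(grade_t3):
        raise ValueError("claw outcome is defined only for claws affected at T3")
    if grade_t4 is None or (isinstance(grade_t4, float) and np.isnan(grade_t4)):
        raise MissingGradeError("T4 grade missing for an affected claw")
    return "recovered" if int(grade_t4) < AFFECTED_THRESHOLD else "chronic"


def _grade_pivot(claws: pd.DataFrame) -> pd.DataFrame:
    """Wide table: index animal, columns (timepoint, limb, side, claw) -> grade."""
    return claws.pivot_table(
        index="animal",
        columns=["timepoint", "limb", "side", "claw"],
        values="grade",
        aggfunc="first",
        dropna=False,
    )


def _timepoint_complete(
    grades: pd.DataFrame, timepoint: str, strict: bool
) -> pd.Series:
    """Whether each animal has a complete lesion record at ``timepoint``.

    Non-strict mode accepts hind-feet-only assessments (all 4 hind claws
    graded, no fore-claw record at all) as complete, mirroring herds where
    only hind feet were examined at calving.
    """
    if timepoint not in grades.columns.get_level_values(0):
        return pd.Series(False, index=grades.index)
    sub = grades[timepoint]
    n_obs = sub.notna().sum(axis=1)
    full = n_obs.eq(8) if sub.shape[1] >= 8 else pd.Series(False, index=grades.index)
    if strict:
        return full
    hind_cols = [c for c in sub.columns if c[0] == "hind"]
    fore_cols = [c for c in sub.columns if c[0] == "fore"]
    hind_full = sub[hind_cols].notna().sum(axis=1).eq(4) if len(hind_cols) == 4 else False
    fore_absent = sub[fore_cols].notna().sum(axis=1).eq(0) if fore_cols else True
    return full | (hind_full & fore_absent)


def derive_traits(records: CohortRecords, strict_completeness: bool = False) -> pd.DataFrame:
    """Derive SL-Susceptibility and SL-Recovery for every animal.

    Returns a long DataFrame (animal, trait, value, interval_days) with
    value NaN for unclassified animals. ``strict_completeness`` controls
    whether hind-feet-only assessments invalidate the resistant
    classification.
    """
    grades = _grade_pivot(records.claws)
    any_affected = grades.ge(AFFECTED_THRESHOLD).any(axis=1)

    complete_all4 = pd.Series(True, index=grades.index)
    for tp in TIMEPOINTS:
        complete_all4 &= _timepoint_complete(grades, tp, strict_completeness)

    susc = pd.Series(np.nan, index=grades.index)
    susc[any_affected] = 1.0
    susc[~any_affected & complete_all4] = 0.0

    # SL-Recovery: complete 8-claw records at both T3 and T4, affected at T3
    rec = pd.Series(np.nan, index=grades.index)
    t3 = grades.get("T3")
    t4 = grades.get("T4")
    if t3 is not None and t4 is not None:
        positions = [c for c in t3.columns if c in t4.columns]
        t3 = t3[positions]
        t4 = t4[positions]
        complete34 = (
            t3.notna().sum(axis=1).eq(8) & t4.notna().sum(axis=1).eq(8)
            if len(positions) == 8
            else pd.Series(False, index=grades.index)
        )
        aff3 = t3.ge(AFFECTED_THRESHOLD)
        in_domain = complete34 & aff3.any(axis=1)
        still = (aff3 & t4.ge(AFFECTED_THRESHOLD)).any(axis=1)
        rec[in_domain & ~still] = 1.0
        rec[in_domain & still] = 0.0

    interval = _t3_t4_interval(records.assessments)

    out = pd.concat(
        [
            pd.DataFrame(
                {
                    "animal": grades.index,
                    "trait": "SL-Susceptibility",
                    "value": susc.to_numpy(),
                    "interval_days": np.nan,
                }
            ),
            pd.DataFrame(
                {
                    "animal": grades.index,
                    "trait": "SL-Recovery",
                    "value": rec.to_numpy(),
                    "interval_days": grades.index.map(interval).to_numpy(dtype=float),
                }
            ),
        ],
        ignore_index=True,
    )
    return out


def _t3_t4_interval(assessments: pd.DataFrame) -> dict:
    if assessments is None or assessments.empty:
        return {}
    days = assessments.pivot_table(
        index="animal", columns="timepoint", values="days_from_calving", aggfunc="first"
    )
    if "T3" not in days.columns or "T4" not in days.columns:
        return {}
    return (days["T4"] - days["T3"]).to_dict()


def _single(records: CohortRecords, animal: int, trait: str, **kw) -> TraitRecord:
    if animal not in set(records.claws["animal"]):
        raise KeyError(f"animal {animal!r} has no lesion records")
    table = derive_traits(records, **kw)
    row = table[(table["animal"] == animal) & (table["trait"] == trait)].iloc[0]
    value = None if np.isnan(row["value"]) else int(row["value"])
    interval = None if np.isnan(row["interval_days"]) else float(row["interval_days"])
    return TraitRecord(animal=animal, trait=trait, value=value, interval_days=interval)


def classify_susceptibility(
    records: CohortRecords, animal: int, strict_completeness: bool = False
) -> TraitRecord:
    """Classify one animal as susceptible (1) / resistant (0) / unclassified."""
    rec = _single(
        records, animal, "SL-Susceptibility", strict_completeness=strict_completeness
    )
    rec.interval_days = None
    return rec


def classify_recovery(records: CohortRecords, animal: int) -> TraitRecord:
    """Classify one animal as recovered (1) / chronic (0) / unclassified."""
    return _single(records, animal, "SL-Recovery")


def prevalence(
    assessments: pd.DataFrame, scope: str = "whole-study"
) -> Prevalence | dict[str, Prevalence]:
    """Lameness prevalence (mobility score 2 or 3).

    ``scope`` is a timepoint name for point prevalence, or ``"whole-study"``
    for period prevalence (lame at any timepoint; denominator = animals with
    at least one mobility score). Animals missing a score at a timepoint
    drop out of that timepoint's denominator only.
    """
    if assessments.empty:
        raise ValueError("no assessments supplied")
    scored = assessments.dropna(subset=["mobility"])
    if scope == "whole-study":
        by_animal = scored.groupby("animal")["mobility"].agg(
            lambda s: s.isin(LAME_SCORES).any()
        )
        if by_animal.empty:
            raise ValueError("no mobility scores in any assessment")
        return Prevalence(int(by_animal.sum()), int(by_animal.size))
    if scope not in TIMEPOINTS:
        raise ValueError(f"scope must be a timepoint or 'whole-study', got {scope!r}")
    sub = scored[scored["timepoint"] == scope]
    if sub.empty:
        raise ValueError(f"no mobility scores at {scope}")
    return Prevalence(int(sub["mobility"].isin(LAME_SCORES).sum()), int(len(sub)))
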