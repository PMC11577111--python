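"""Phenotype handling: BMI computation, sex x BMI partitioning, healthy-subject
filtering, and median-phenotype reference selection.

The cohort is split into six groups (female/male x normal/overweight/obese)
using the WHO BMI cut-offs: normal [18.5, 25), overweight [25, 30), obese
>= 30.  Each group's reference subject is the one closest (in MAD-standardised
Euclidean distance) to the component-wise median of age, weight, height, BMI
and body-fat percentage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
BMI_CATEGORIES = ("normal", "overweight", "obese")
#: lower inclusion bound; half-open ranges, boundary 30 -> obese
BMI_RANGES = {
    "normal": (18.5, 25.0),
    "overweight": (25.0, 30.0),
    "obese": (30.0, math.inf),
}
REFERENCE_PHENOTYPES = ("age", "weight", "height", "bmi", "body_fat")

HEALTH_FLAGS = ("cancer_record", "self_reported_disease", "operation_history")


class ExclusionError(ValueError):
    """Subject cannot be assigned to any study group."""


@dataclass
class SubjectRecord:
    """Phenotypes and health flags for one subject."""

    subject_id: str
    sex: str
    age: float
    weight: float  # kg
    height: float  # cm
    body_fat: float  # percent
    bmi: float | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        if not 0 <= self.body_fat <= 100:
            raise ValueError("body_fat must be a percentage in [0, 100]")
        derived = compute_bmi(self.weight, self.height, decimals=None)
        if self.bmi is None:
            self.bmi = derived
        elif abs(self.bmi - derived) > 0.05:
            raise ValueError(
                f"declared bmi {self.bmi} inconsistent with weight/height ({derived:.2f})"
            )


@dataclass(frozen=True)
class GroupAssignment:
    sex: str
    category: str
    bmi_range: tuple[float, float]

    @property
    def name(self) -> str:
        return f"{self.sex}-{self.category}"


def compute_bmi(weight: float, height: float, decimals: int | None = 1) -> float:
    """Body-mass index, weight(kg) / height(m)^2; height given in cm.

    ``decimals=1`` matches the one-decimal display convention; pass ``None``
    for the unrounded value.
    """
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight / (height / 100.0) ** 2
    return round(bmi, decimals) if decimals is not None else bmi


def assign_group(sex: str, bmi: float) -> GroupAssignment:
    """Map (sex, BMI) to one of the six study groups.

    Ranges are half-open so the six groups partition sex x [18.5, inf);
    a BMI of exactly 30 is obese.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    for category in BMI_CATEGORIES:
        lo, hi = BMI_RANGES[category]
        if lo <= bmi < hi:
            return GroupAssignment(sex, category, (lo, hi))
    raise ExclusionError(f"BMI {bmi} below inclusion bound {BMI_RANGES['normal'][0]}")


def filter_healthy(records: Iterable[SubjectRecord]) -> list[SubjectRecord]:
    """Keep subjects with no cancer record, no self-reported disease and no
    operation history.

    A missing flag excludes the subject (unknown health status is treated
    conservatively); every exclusion is logged with its reason.
    """
    kept: list[SubjectRecord] = []
    for rec in records:
        reason = None
        for flag in HEALTH_FLAGS:
            value = rec.flags.get(flag)
            if value is None:
                reason = f"unknown health status ({flag} missing)"
                break
            if bool(value):
                reason = f"{flag} is positive"
                break
        if reason is None:
            kept.append(rec)
        else:
            logger.info("excluding subject %s: %s", rec.subject_id, reason)
    return kept


def select_reference(records: Sequence[SubjectRecord]) -> str:
    """Select the subject closest to the group's median phenotype vector.

    Each of (age, weight, height, BMI, body-fat %) is standardised by the
    group's median absolute deviation so no unit dominates; the subject with
    the smallest Euclidean distance to the median vector wins, ties broken by
    lowest subject id.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot select a reference from an empty group")
    X = np.array(
        [[getattr(r, p) for p in REFERENCE_PHENOTYPES] for r in records], dtype=float
    )
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    scale = np.where(mad > 0, mad, 1.0)
    dist = np.sqrt((((X - med) / scale) ** 2).sum(axis=1))
    order = sorted(range(len(records)), key=lambda i: (dist[i], records[i].subject_id))
    best = records[order[0]]
    logger.info(
        "reference for group: %s (phenotypes %s, distance %.4f)",
        best.subject_id,
        {p: getattr(best, p) for p in REFERENCE_PHENOTYPES},
        dist[order[0]],
    )
    return best.subject_id


# ---------------------------------------------------------------------------
# tabular I/O

PHENOTYPE_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "weight",
    "height",
    "bmi",
    "body_fat",
    "cancer_record",
    "self_reported_disease",
    "operation_history",
]


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            "age": r.age,
            "weight": r.weight,
            "height": r.height,
            "bmi": r.bmi,
            "body_fat": r.body_fat,
        }
        for flag in HEALTH_FLAGS:
            row[flag] = bool(r.flags.get(flag, False))
        rows.append(row)
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                weight=float(row["weight"]),
                height=float(row["height"]),
                body_fat=float(row["body_fat"]),
                bmi=None if pd.isna(row["bmi"]) else float(row["bmi"]),
                flags={f: None if pd.isna(row[f]) else bool(row[f]) for f in HEALTH_FLAGS},
            )
        )
    return records


def read_phenotypes(path) -> list[SubjectRecord]:
    """Read a phenotype CSV/TSV with the documented header."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return frame_to_records(pd.read_csv(path, sep=sep))


def write_phenotypes(records: Iterable[SubjectRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
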