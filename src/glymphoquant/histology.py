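"""Semi-quantitative colonic histopathology scoring.

Seven ordinal features are graded per H&E section by a blinded rater:
depth of inflammation (0-4), inflammatory cell infiltration (0-3), crypt
damage (0-4), crypt abscess (0-2), submucosal edema (0-3), goblet-cell
loss (0-3) and crypt epithelial hyperplasia (0-3).  The composite score is
the sum of all seven subscores (range 0-22); the infiltration subscore and
the epithelial-injury subtotal (the other six features) are also emitted
separately so either component can be reported on its own.  Per-animal
scores are the mean over that animal's sections.

Grading itself is manual; this module only validates and aggregates.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

#: Maximum grade per rubric feature, in canonical column order.
FEATURE_MAX: dict[str, int] = {
    "inflammation_depth": 4,
    "infiltration": 3,
    "crypt_damage": 4,
    "crypt_abscess": 2,
    "submucosal_edema": 3,
    "goblet_loss": 3,
    "crypt_hyperplasia": 3,
}

#: Composite score ceiling (sum of the per-feature maxima).
MAX_COMPOSITE = sum(FEATURE_MAX.values())  # 22

FEATURES = tuple(FEATURE_MAX)


@dataclass(frozen=True)
class HistologyGrades:
    """The seven ordinal subscores for one section of one animal."""

    animal_id: str
    section_id: str
    inflammation_depth: int
    infiltration: int
    crypt_damage: int
    crypt_abscess: int
    submucosal_edema: int
    goblet_loss: int
    crypt_hyperplasia: int

    def __post_init__(self) -> None:
        for name, maximum in FEATURE_MAX.items():
            value = getattr(self, name)
            if isinstance(value, bool):
                raise ValueError(f"{name} must be an integer grade, got {value!r}")
            if isinstance(value, numbers.Integral):
                value = int(value)
            elif isinstance(value, numbers.Real) and float(value).is_integer():
                value = int(value)  # CSV readers often promote integer grades to float
            else:
                raise ValueError(f"{name} must be an integer grade, got {value!r}")
            object.__setattr__(self, name, value)
            if not 0 <= value <= maximum:
                raise ValueError(
                    f"{name} = {value} outside its rubric range 0..{maximum}"
                )


def validate_grades(record: Mapping[str, object]) -> HistologyGrades:
    """Build validated grades from a mapping, naming any offending field.

    Requires ``animal_id``, ``section_id`` and all seven feature columns;
    non-integer or out-of-range grades are rejected.
    """
    expected = {"animal_id", "section_id", *FEATURES}
    missing = expected - set(record)
    if missing:
        raise KeyError(f"grade record is missing fields: {sorted(missing)}")
    return HistologyGrades(
        animal_id=str(record["animal_id"]),
        section_id=str(record["section_id"]),
        **{name: record[name] for name in FEATURES},  # type: ignore[arg-type]
    )


def composite_score(grades: HistologyGrades) -> int:
    """Sum of all seven subscores (0-22)."""
    return sum(getattr(grades, name) for name in FEATURES)


def epithelial_injury_score(grades: HistologyGrades) -> int:
    """Subtotal over the six non-infiltration features (0-19)."""
    return composite_score(grades) - grades.infiltration


def animal_score(section_scores: Sequence[float]) -> float:
    """Mean composite over an animal's sections (order-independent)."""
    if len(section_scores) == 0:
        raise ValueError("animal has no section scores")
    return float(sum(section_scores)) / len(section_scores)


def score_table(grades: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a long table of per-section grades.

    ``grades`` needs columns ``animal_id, section_id`` plus the seven
    feature columns (an optional ``group`` column is carried through).
    Returns ``(per_section, per_animal)``: the per-section frame adds
    ``infiltration_score``, ``epithelial_injury_score`` and ``composite``;
    the per-animal frame holds the mean composite and section count.
    """
    records = grades.to_dict("records")
    validated = [validate_grades(rec) for rec in records]
    per_section = grades.copy().reset_index(drop=True)
    per_section["infiltration_score"] = [g.infiltration for g in validated]
    per_section["epithelial_injury_score"] = [epithelial_injury_score(g) for g in validated]
    per_section["composite"] = [composite_score(g) for g in validated]

    keys = ["animal_id", "group"] if "group" in per_section.columns else ["animal_id"]
    per_animal = (
        per_section.groupby(keys, sort=True)["composite"]
        .agg(mean_composite="mean", n_sections="count")
        .reset_index()
    )
    return per_section, per_animal


def read_grades_csv(path) -> pd.DataFrame:
    """Read a per-section grade table and validate every record."""
    frame = pd.read_csv(path)
    for rec in frame.to_dict("records"):
        validate_grades(rec)
    return frame
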