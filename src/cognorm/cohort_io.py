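"""Cohort table I/O, validation, and the outcome registry.

A cohort is a CSV with one row per participant: ``id``, ``age`` (integer
years), ``sex`` (male/female), ``education_level`` (ordinal 1–6), optional
``country`` and ``fullscreen`` columns, and one column per cognitive
outcome.  The six bundled outcomes come from three CANTAB tests:

========  =========  ==========  ============  =============
name      family     range       direction     offset
========  =========  ==========  ============  =============
PALTEA    zoib       0–70        lower_better  –
PALFAMS   zoib       0–20        higher_better –
SWMBE     hurdle_nb  0–153       lower_better  0
SWMS      hurdle_nb  2–14        lower_better  2
RVPA      beta       0–1         higher_better –
RVPPFA    zoib       0–1         lower_better  –
========  =========  ==========  ============  =============

Education levels 1–6 (left school before 16 ... PhD) are collapsed to a
low/high band; by default only level 1 ("left formal education before age
16") maps to low, matching the definition of low as leaving school before
age 16.  The alternative grouping {1, 2} (at or before 16) is available via
``education_low_levels``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeSpec",
    "ParticipantRecord",
    "ValidationError",
    "ValidationReport",
    "DEFAULT_OUTCOMES",
    "DEFAULT_EDUCATION_LOW_LEVELS",
    "collapse_education",
    "load_cohort",
    "write_cohort",
    "cohort_to_frame",
    "records_from_frame",
    "encode_design",
]

DEFAULT_EDUCATION_LOW_LEVELS: frozenset[int] = frozenset({1})
AGE_BOUNDS = (18, 75)

SEX_CODES = {"male": 0, "female": 1}       # regression coding
EDU_CODES = {"low": 0, "high": 1}


class ValidationError(ValueError):
    """A cohort row or value violates an invariant."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Metadata for one cognitive outcome measure.

    ``direction`` states whether larger raw scores mean better performance;
    ``offset`` shifts the hurdle-NB count support (SWMS has floor 2, the
    family has support at 0).  Unit-interval families (beta/zoib) require a
    finite range so raw scores can be rescaled to [0,1].
    """

    name: str
    family: str
    direction: str
    score_min: float
    score_max: float
    offset: int = 0
    integer_scored: bool = False

    def __post_init__(self):
        if self.family not in ("beta", "zoib", "hurdle_nb"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"{self.name}: bad direction {self.direction!r}")
        if not self.score_min < self.score_max:
            raise ValueError(f"{self.name}: score_min must be < score_max")
        if self.family in ("beta", "zoib") and not (
            np.isfinite(self.score_min) and np.isfinite(self.score_max)
        ):
            raise ValueError(f"{self.name}: unit-interval family needs a finite range")

    @property
    def span(self) -> float:
        return self.score_max - self.score_min

    def to_unit(self, score):
        """Rescale a raw score to the unit interval (beta/zoib families)."""
        return (np.asarray(score, dtype=float) - self.score_min) / self.span

    def from_unit(self, u):
        """Inverse of :meth:`to_unit`; rounds half-away-from-zero for
        integer-scored outcomes."""
        raw = np.asarray(u, dtype=float) * self.span + self.score_min
        if self.integer_scored:
            raw = np.floor(np.abs(raw) + 0.5) * np.sign(raw)
        return raw

    def to_count(self, score):
        """Raw score -> hurdle-NB count (subtract the support offset)."""
        return np.asarray(score) - self.offset

    def from_count(self, count):
        return np.asarray(count) + self.offset


DEFAULT_OUTCOMES: dict[str, OutcomeSpec] = {
    s.name: s
    for s in (
        OutcomeSpec("PALTEA", "zoib", "lower_better", 0, 70, integer_scored=True),
        OutcomeSpec("PALFAMS", "zoib", "higher_better", 0, 20, integer_scored=True),
        OutcomeSpec("SWMBE", "hurdle_nb", "lower_better", 0, 153, offset=0,
                    integer_scored=True),
        OutcomeSpec("SWMS", "hurdle_nb", "lower_better", 2, 14, offset=2,
                    integer_scored=True),
        OutcomeSpec("RVPA", "beta", "higher_better", 0, 1),
        OutcomeSpec("RVPPFA", "zoib", "lower_better", 0, 1),
    )
}


def collapse_education(
    level: int,
    education_low_levels: Iterable[int] = DEFAULT_EDUCATION_LOW_LEVELS,
    record_id: str | None = None,
) -> str:
    """Collapse ordinal education level 1–6 into the low/high band.

    Low means leaving formal education before age 16; under the default
    mapping that is level 1 only.
    """
    try:
        level = int(level)
    except (TypeError, ValueError):
        raise ValidationError(
            f"education_level {level!r} is not an integer"
            + (f" (record {record_id})" if record_id else "")
        )
    if level not in range(1, 7):
        raise ValidationError(
            f"education_level must be 1..6, got {level}"
            + (f" (record {record_id})" if record_id else "")
        )
    return "low" if level in set(education_low_levels) else "high"


@dataclass
class ParticipantRecord:
    """One subject: demographics plus a mapping outcome name -> score."""

    id: str
    age: int
    sex: str
    education_level: int
    education_band: str = ""
    country: str | None = None
    fullscreen: bool | None = None
    scores: dict[str, float] = field(default_factory=dict)

    def score(self, outcome: str):
        return self.scores.get(outcome)


@dataclass
class ValidationReport:
    n_read: int = 0
    n_kept: int = 0
    rejected: list[dict] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_read": self.n_read,
                "n_kept": self.n_kept,
                "n_rejected": self.n_rejected,
                "rejected": self.rejected,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


_MANDATORY = ("id", "age", "sex", "education_level")


def _validate_row(
    row: Mapping,
    specs: Mapping[str, OutcomeSpec],
    age_bounds: tuple[int, int],
    education_low_levels: Iterable[int],
) -> ParticipantRecord:
    rid = str(row["id"])
    try:
        age = int(row["age"])
    except (TypeError, ValueError):
        raise ValidationError(f"record {rid}: unparseable age {row['age']!r}")
    lo, hi = age_bounds
    if not lo <= age <= hi:
        raise ValidationError(f"record {rid}: age {age} outside [{lo}, {hi}]")
    sex = str(row["sex"]).strip().lower()
    if sex not in SEX_CODES:
        raise ValidationError(f"record {rid}: sex must be male/female, got {sex!r}")
    band = collapse_education(row["education_level"], education_low_levels, rid)

    scores: dict[str, float] = {}
    for name, spec in specs.items():
        if name not in row or pd.isna(row[name]):
            continue
        try:
            val = float(row[name])
        except (TypeError, ValueError):
            raise ValidationError(f"record {rid}: unparseable {name} {row[name]!r}")
        if not spec.score_min <= val <= spec.score_max:
            raise ValidationError(
                f"record {rid}: {name}={val} outside "
                f"[{spec.score_min}, {spec.score_max}]"
            )
        scores[name] = val

    return ParticipantRecord(
        id=rid,
        age=age,
        sex=sex,
        education_level=int(row["education_level"]),
        education_band=band,
        country=(None if "country" not in row or pd.isna(row["country"])
                 else str(row["country"])),
        fullscreen=(None if "fullscreen" not in row or pd.isna(row["fullscreen"])
                    else bool(row["fullscreen"])),
        scores=scores,
    )


def load_cohort(
    path,
    specs: Mapping[str, OutcomeSpec] | None = None,
    age_bounds: tuple[int, int] = AGE_BOUNDS,
    education_low_levels: Iterable[int] = DEFAULT_EDUCATION_LOW_LEVELS,
) -> tuple[list[ParticipantRecord], ValidationReport]:
    """Read and validate a cohort CSV.

    Rows violating any invariant are rejected with a per-row diagnostic in
    the returned :class:`ValidationReport`; valid rows are kept.  Duplicate
    ids and missing mandatory columns are errors for the whole file.
    """
    specs = dict(DEFAULT_OUTCOMES if specs is None else specs)
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {missing}")
    if not any(name in df.columns for name in specs):
        raise ValidationError("no outcome column found in cohort CSV")
    dup = df["id"].astype(str).duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate id(s): {sorted(df.loc[dup, 'id'].astype(str).unique())}"
        )

    report = ValidationReport(n_read=len(df))
    records: list[ParticipantRecord] = []
    for _, row in df.iterrows():
        try:
            records.append(
                _validate_row(row, specs, age_bounds, education_low_levels)
            )
        except ValidationError as exc:
            report.rejected.append({"id": str(row["id"]), "reason": str(exc)})
    report.n_kept = len(records)
    return records, report


def cohort_to_frame(records: Sequence[ParticipantRecord],
                    specs: Mapping[str, OutcomeSpec] | None = None) -> pd.DataFrame:
    """Tidy DataFrame view of a cohort (one row per participant)."""
    specs = DEFAULT_OUTCOMES if specs is None else specs
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "education_level": r.education_level,
            "education_band": r.education_band,
        }
        if r.country is not None:
            row["country"] = r.country
        if r.fullscreen is not None:
            row["fullscreen"] = r.fullscreen
        for name in specs:
            if name in r.scores:
                row[name] = r.scores[name]
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(
    df: pd.DataFrame,
    specs: Mapping[str, OutcomeSpec] | None = None,
    age_bounds: tuple[int, int] = AGE_BOUNDS,
    education_low_levels: Iterable[int] = DEFAULT_EDUCATION_LOW_LEVELS,
) -> list[ParticipantRecord]:
    """Validate an in-memory cohort frame into records (strict: raises)."""
    specs = dict(DEFAULT_OUTCOMES if specs is None else specs)
    return [
        _validate_row(row, specs, age_bounds, education_low_levels)
        for _, row in df.iterrows()
    ]


def write_cohort(records: Sequence[ParticipantRecord], path,
                 specs: Mapping[str, OutcomeSpec] | None = None) -> None:
    """Write a cohort CSV (comma-separated, UTF-8, '.' decimals)."""
    cohort_to_frame(records, specs).to_csv(path, index=False)


def encode_design(df: pd.DataFrame, age_center: float = 40.0) -> pd.DataFrame:
    """Add numeric regression codings: sex male=0/female=1, education band
    low=0/high=1, and centred age."""
    out = df.copy()
    out["sex_code"] = out["sex"].map(SEX_CODES).astype(float)
    out["edu_code"] = out["education_band"].map(EDU_CODES).astype(float)
    out["age_c"] = out["age"].astype(float) - age_center
    return out
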