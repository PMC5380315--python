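"""Cohort data model and harmonization rules for screening-trial-like data.

A cohort is a list of :class:`Subject` records (one per person, with explicit
missing-value support) plus, optionally, a list of :class:`OutcomeRecord`
entries carrying the binary lung-cancer incidence/death outcomes observed
within a fixed follow-up horizon (6 years by default).

The module also implements the data-hygiene rules applied before model
evaluation — recoding implausible smoking intensities (>100 cigarettes/day)
and body-mass indices (outside 14–60 kg/m2) to the nearest plausible bound —
and the pack-year-based screening-eligibility criterion used by the NLST and
the USPSTF recommendations (>=30 pack-years; if a former smoker, quit <15
years ago).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "SmokingHistory",
    "Subject",
    "OutcomeRecord",
    "ChangeLogEntry",
    "RowError",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "recode_implausible",
    "pack_years",
    "nlst_eligible",
    "exclude_never_smokers",
    "cohort_frame",
    "subjects_from_frame",
]

GENDERS = ("male", "female")
RACES = ("white", "black", "hispanic", "asian", "pacific_islander", "native_american")
SMOKING_STATUSES = ("current", "former", "never")

INTENSITY_MAX = 100.0
BMI_MIN = 14.0
BMI_MAX = 60.0

#: Declared relative tolerance for reported pack-years vs duration*intensity/20.
PACK_YEAR_TOLERANCE = 0.10


class CohortSchemaError(ValueError):
    """Raised when a cohort file is missing mandatory columns or uses an
    unknown schema version."""


@dataclass(frozen=True)
class RowError:
    """A row that could not be parsed; reported, never silently dropped."""

    row_index: int
    message: str


@dataclass(frozen=True)
class ChangeLogEntry:
    id: str
    field: str
    old: float
    new: float


@dataclass(frozen=True)
class SmokingHistory:
    """Smoking exposure summary as collected by trial questionnaires.

    ``status`` is ``current``/``former`` (``never`` is parseable but rejected
    for model evaluation); ``duration`` in years, ``intensity`` in cigarettes
    per day, ``years_since_quit`` in years (0 for current smokers).
    ``pack_years`` may be reported independently of duration*intensity/20;
    disagreements beyond :data:`PACK_YEAR_TOLERANCE` are flagged, not fixed.
    """

    status: Optional[str] = None
    duration: Optional[float] = None
    intensity: Optional[float] = None
    years_since_quit: Optional[float] = None
    pack_years: Optional[float] = None

    def derived_pack_years(self) -> Optional[float]:
        """duration * intensity / 20, propagating missingness."""
        return pack_years(self.duration, self.intensity)

    def effective_pack_years(self) -> Optional[float]:
        """Reported pack-years when available, else the derived value."""
        if self.pack_years is not None:
            return self.pack_years
        return self.derived_pack_years()

    def pack_years_consistent(self, tolerance: float = PACK_YEAR_TOLERANCE) -> bool:
        """Whether reported and derived pack-years agree within ``tolerance``.

        Vacuously true when either quantity is unavailable.
        """
        derived = self.derived_pack_years()
        if derived is None or self.pack_years is None:
            return True
        if derived == 0:
            return self.pack_years == 0
        return abs(self.pack_years - derived) <= tolerance * derived


@dataclass(frozen=True)
class Subject:
    """One person's risk-factor profile. Every field except ``id`` and
    ``age`` may be missing (``None``)."""

    id: str
    age: float
    gender: Optional[str] = None
    race: Optional[str] = None
    education: Optional[int] = None  # ordinal 1-6
    bmi: Optional[float] = None
    copd: Optional[bool] = None
    emphysema: Optional[bool] = None
    personal_history_cancer: Optional[bool] = None
    family_history_lc: Optional[bool] = None
    history_pneumonia: Optional[bool] = None
    asbestos: Optional[bool] = None
    smoking: SmokingHistory = field(default_factory=SmokingHistory)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when clean)."""
        problems: list[str] = []
        if not 18 <= self.age <= 110:
            problems.append(f"age {self.age} outside [18, 110]")
        if self.bmi is not None and not BMI_MIN <= self.bmi <= BMI_MAX:
            problems.append(f"bmi {self.bmi} outside [{BMI_MIN}, {BMI_MAX}]")
        if self.education is not None and self.education not in range(1, 7):
            problems.append(f"education {self.education} outside 1..6")
        s = self.smoking
        if s.duration is not None and s.duration >= self.age:
            problems.append(f"smoking duration {s.duration} >= age {self.age}")
        if s.intensity is not None and s.intensity > INTENSITY_MAX:
            problems.append(f"intensity {s.intensity} > {INTENSITY_MAX}")
        if s.status == "current" and s.years_since_quit not in (None, 0, 0.0):
            problems.append("current smoker with years_since_quit != 0")
        if s.status == "former" and s.years_since_quit is not None and s.years_since_quit <= 0:
            problems.append("former smoker with years_since_quit <= 0")
        if not s.pack_years_consistent():
            problems.append(
                "reported pack-years inconsistent with duration*intensity/20 "
                f"({s.pack_years} vs {s.derived_pack_years():.2f})"
            )
        return problems


@dataclass(frozen=True)
class OutcomeRecord:
    """Binary outcomes within a fixed follow-up horizon."""

    id: str
    lc_incidence: bool
    lc_death: bool
    horizon: float = 6.0


def pack_years(duration: Optional[float], intensity: Optional[float]) -> Optional[float]:
    """Cumulative smoking exposure: years smoked x cigarettes/day / 20.

    Missing inputs propagate to a missing result.
    """
    if duration is None or intensity is None:
        return None
    if duration < 0 or intensity < 0:
        raise ValueError("duration and intensity must be >= 0")
    return duration * intensity / 20.0


def nlst_eligible(
    subject: Subject,
    age_min: Optional[float] = None,
    age_max: Optional[float] = None,
) -> Optional[bool]:
    """Pack-year-based screening eligibility.

    True iff pack-years >= 30 and (current smoker or quit < 15 years ago).
    The optional age window (e.g. 55-74 for the NLST enrollment criteria,
    55-80 for the USPSTF recommendation) defaults to none, matching the
    criterion as applied to an already-enrolled cohort.

    Returns ``None`` (indeterminate, not ``False``) when the smoking fields
    required by the criterion are missing.
    """
    if age_min is not None and subject.age < age_min:
        return False
    if age_max is not None and subject.age > age_max:
        return False
    s = subject.smoking
    if s.status == "never":
        return False
    py = s.effective_pack_years()
    if py is None or s.status is None:
        return None
    if py < 30.0:
        return False
    if s.status == "current":
        return True
    if s.years_since_quit is None:
        return None
    return s.years_since_quit < 15.0


def recode_implausible(
    subjects: Sequence[Subject],
) -> tuple[list[Subject], list[ChangeLogEntry]]:
    """Recode implausible values to the nearest plausible bound.

    Smoking intensities above 100 cigarettes/day become 100; BMI below 14 or
    above 60 kg/m2 becomes 14 or 60. Idempotent; every change is logged with
    subject id, field, old and new value.
    """
    out: list[Subject] = []
    log: list[ChangeLogEntry] = []
    for subj in subjects:
        s = subj.smoking
        new_smoking = s
        if s.intensity is not None and s.intensity > INTENSITY_MAX:
            log.append(ChangeLogEntry(subj.id, "smoking_intensity", s.intensity, INTENSITY_MAX))
            new_smoking = replace(s, intensity=INTENSITY_MAX)
        new_subj = subj if new_smoking is s else replace(subj, smoking=new_smoking)
        if subj.bmi is not None:
            if subj.bmi < BMI_MIN:
                log.append(ChangeLogEntry(subj.id, "bmi", subj.bmi, BMI_MIN))
                new_subj = replace(new_subj, bmi=BMI_MIN)
            elif subj.bmi > BMI_MAX:
                log.append(ChangeLogEntry(subj.id, "bmi", subj.bmi, BMI_MAX))
                new_subj = replace(new_subj, bmi=BMI_MAX)
        out.append(new_subj)
    return out, log


def write_change_log(log: Sequence[ChangeLogEntry], path) -> None:
    """Write a recoding change log as tab-separated text."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "field", "old", "new"])
        for entry in log:
            writer.writerow([entry.id, entry.field, entry.old, entry.new])


def exclude_never_smokers(
    subjects: Sequence[Subject],
) -> tuple[list[Subject], list[str]]:
    """Drop never-smokers (risk models apply to ever-smokers only).

    Returns the retained subjects and a list of warnings naming each
    excluded id.
    """
    kept: list[Subject] = []
    warnings: list[str] = []
    for s in subjects:
        if s.smoking.status == "never":
            warnings.append(f"subject {s.id}: never-smoker excluded from model evaluation")
        else:
            kept.append(s)
    return kept, warnings


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: comma-separated, UTF-8, header row, empty string = missing.
# ---------------------------------------------------------------------------

SUBJECT_COLUMNS = [
    "id",
    "age",
    "gender",
    "race",
    "education",
    "bmi",
    "copd",
    "emphysema",
    "personal_history_cancer",
    "family_history_lc",
    "history_pneumonia",
    "asbestos",
    "smoking_status",
    "smoking_duration",
    "smoking_intensity",
    "years_since_quit",
    "pack_years",
]
OUTCOME_COLUMNS = ["lc_incidence", "lc_death", "horizon"]
MANDATORY_COLUMNS = ("id", "age")
SCHEMA_VERSIONS = ("1",)

_BOOL_FIELDS = (
    "copd",
    "emphysema",
    "personal_history_cancer",
    "family_history_lc",
    "history_pneumonia",
    "asbestos",
)


def _parse_float(value: str, column: str) -> Optional[float]:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"non-numeric value {value!r} in column {column!r}") from None


def _parse_bool(value: str, column: str) -> Optional[bool]:
    if value == "":
        return None
    v = value.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise ValueError(f"non-boolean value {value!r} in column {column!r}")


def _parse_enum(value: str, column: str, allowed: tuple[str, ...]) -> Optional[str]:
    if value == "":
        return None
    v = value.strip().lower()
    if v not in allowed:
        raise ValueError(f"value {value!r} in column {column!r} not one of {allowed}")
    return v


def read_cohort(
    path, schema_version: str = "1"
) -> tuple[list[Subject], list[OutcomeRecord], list[RowError]]:
    """Read a cohort CSV.

    Returns (subjects, outcomes, row_errors). Outcome records are produced
    only when the file carries outcome columns. Unparseable rows are
    collected in ``row_errors`` with their (0-based, data-row) index rather
    than silently dropped. Missing mandatory columns raise
    :class:`CohortSchemaError`.
    """
    if schema_version not in SCHEMA_VERSIONS:
        raise CohortSchemaError(f"unknown schema version {schema_version!r}")
    subjects: list[Subject] = []
    outcomes: list[OutcomeRecord] = []
    errors: list[RowError] = []
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise CohortSchemaError(f"missing mandatory column {col!r}")
        has_outcomes = "lc_incidence" in header
        for i, row in enumerate(reader):
            try:
                subjects.append(_subject_from_row(row))
                if has_outcomes and (row.get("lc_incidence") or "") != "":
                    outcomes.append(
                        OutcomeRecord(
                            id=row["id"],
                            lc_incidence=bool(_parse_bool(row["lc_incidence"], "lc_incidence")),
                            lc_death=bool(_parse_bool(row.get("lc_death", "0") or "0", "lc_death")),
                            horizon=_parse_float(row.get("horizon", "") or "6", "horizon") or 6.0,
                        )
                    )
            except (ValueError, KeyError) as exc:
                errors.append(RowError(i, str(exc)))
    return subjects, outcomes, errors


def _subject_from_row(row: dict) -> Subject:
    sid = (row.get("id") or "").strip()
    if sid == "":
        raise ValueError("empty id")
    age = _parse_float(row.get("age") or "", "age")
    if age is None:
        raise ValueError("missing age")
    edu = _parse_float(row.get("education", "") or "", "education")
    smoking = SmokingHistory(
        status=_parse_enum(row.get("smoking_status", "") or "", "smoking_status", SMOKING_STATUSES),
        duration=_parse_float(row.get("smoking_duration", "") or "", "smoking_duration"),
        intensity=_parse_float(row.get("smoking_intensity", "") or "", "smoking_intensity"),
        years_since_quit=_parse_float(row.get("years_since_quit", "") or "", "years_since_quit"),
        pack_years=_parse_float(row.get("pack_years", "") or "", "pack_years"),
    )
    return Subject(
        id=sid,
        age=age,
        gender=_parse_enum(row.get("gender", "") or "", "gender", GENDERS),
        race=_parse_enum(row.get("race", "") or "", "race", RACES),
        education=None if edu is None else int(edu),
        bmi=_parse_float(row.get("bmi", "") or "", "bmi"),
        copd=_parse_bool(row.get("copd", "") or "", "copd"),
        emphysema=_parse_bool(row.get("emphysema", "") or "", "emphysema"),
        personal_history_cancer=_parse_bool(
            row.get("personal_history_cancer", "") or "", "personal_history_cancer"
        ),
        family_history_lc=_parse_bool(row.get("family_history_lc", "") or "", "family_history_lc"),
        history_pneumonia=_parse_bool(row.get("history_pneumonia", "") or "", "history_pneumonia"),
        asbestos=_parse_bool(row.get("asbestos", "") or "", "asbestos"),
        smoking=smoking,
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and float(value).is_integer():
        return str(int(value))
    return str(value)


def write_cohort(
    subjects: Sequence[Subject],
    path,
    outcomes: Optional[Sequence[OutcomeRecord]] = None,
) -> None:
    """Write a cohort CSV that round-trips through :func:`read_cohort`,
    including missingness. Row order is the input order (deterministic)."""
    by_id = {o.id: o for o in outcomes} if outcomes else {}
    columns = SUBJECT_COLUMNS + (OUTCOME_COLUMNS if outcomes else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for s in subjects:
            row = [
                s.id,
                _fmt(s.age),
                _fmt(s.gender),
                _fmt(s.race),
                _fmt(s.education),
                _fmt(s.bmi),
                _fmt(s.copd),
                _fmt(s.emphysema),
                _fmt(s.personal_history_cancer),
                _fmt(s.family_history_lc),
                _fmt(s.history_pneumonia),
                _fmt(s.asbestos),
                _fmt(s.smoking.status),
                _fmt(s.smoking.duration),
                _fmt(s.smoking.intensity),
                _fmt(s.smoking.years_since_quit),
                _fmt(s.smoking.pack_years),
            ]
            if outcomes:
                o = by_id.get(s.id)
                row += [_fmt(o.lc_incidence), _fmt(o.lc_death), _fmt(o.horizon)] if o else ["", "", ""]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# DataFrame bridge (used by the vectorized model implementations)
# ---------------------------------------------------------------------------

def cohort_frame(subjects: Iterable[Subject]):
    """Typed pandas DataFrame view of a cohort (NaN encodes missing)."""
    import pandas as pd

    rows = []
    for s in subjects:
        rows.append(
            {
                "id": s.id,
                "age": s.age,
                "gender": s.gender,
                "race": s.race,
                "education": s.education,
                "bmi": s.bmi,
                "copd": s.copd,
                "emphysema": s.emphysema,
                "personal_history_cancer": s.personal_history_cancer,
                "family_history_lc": s.family_history_lc,
                "history_pneumonia": s.history_pneumonia,
                "asbestos": s.asbestos,
                "smoking_status": s.smoking.status,
                "smoking_duration": s.smoking.duration,
                "smoking_intensity": s.smoking.intensity,
                "years_since_quit": s.smoking.years_since_quit,
                "pack_years": s.smoking.effective_pack_years(),
            }
        )
    df = pd.DataFrame(rows)
    for col in ("age", "education", "bmi", "smoking_duration", "smoking_intensity",
                "years_since_quit", "pack_years"):
        df[col] = pd.to_numeric(df[col])
    return df


def subjects_from_frame(df) -> list[Subject]:
    """Inverse of :func:`cohort_frame` (NaN back to None)."""

    def _none(v):
        if v is None:
            return None
        if isinstance(v, float) and math.isnan(v):
            return None
        return v

    def _bool(v):
        v = _none(v)
        return None if v is None else bool(v)

    subjects = []
    for row in df.itertuples(index=False):
        edu = _none(row.education)
        subjects.append(
            Subject(
                id=str(row.id),
                age=float(row.age),
                gender=_none(row.gender),
                race=_none(row.race),
                education=None if edu is None else int(edu),
                bmi=_none(row.bmi),
                copd=_bool(row.copd),
                emphysema=_bool(row.emphysema),
                personal_history_cancer=_bool(row.personal_history_cancer),
                family_history_lc=_bool(row.family_history_lc),
                history_pneumonia=_bool(row.history_pneumonia),
                asbestos=_bool(row.asbestos),
                smoking=SmokingHistory(
                    status=_none(row.smoking_status),
                    duration=_none(row.smoking_duration),
                    intensity=_none(row.smoking_intensity),
                    years_since_quit=_none(row.years_since_quit),
                    pack_years=_none(row.pack_years),
                ),
            )
        )
    return subjects
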