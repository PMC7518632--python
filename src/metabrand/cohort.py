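"""Participant records, covariate binning, and cohort-table I/O.

Five participant-level variables are carried alongside each MRI scan:
age, gender, education, marital status, and APOE-ε4 carrier status.
Continuous variables (age, education in years) are reduced to the small
categorical groupings used throughout the pipeline; the categorical
variables pass through unchanged.  Two age-binning schemes exist because
the two study populations span different age ranges (the population
cohort tops out at 85, the ADNI-style cohort at 90); they differ only in
the upper bin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Scheme",
    "ParticipantRecord",
    "BinnedMetadata",
    "CohortTable",
    "VARIABLE_ORDER",
    "CATEGORY_ORDERS",
    "bin_age",
    "bin_education",
    "bin_record",
    "read_cohort_table",
    "write_cohort_table",
    "CohortError",
]


class CohortError(ValueError):
    """Raised for malformed covariate values or cohort tables."""


class Scheme(str, enum.Enum):
    """Age-binning scheme; the two differ only in the top bin."""

    HNR = "HNR"
    ADNI = "ADNI"


GENDERS = ("Female", "Male")
MARITAL_STATUSES = ("Married", "Widowed", "Divorced", "Single")
APOE4_STATUSES = ("Positive", "Negative")
LABELS = ("aMCI", "Control")

EDUCATION_BINS = ("<=10", "11-13", ">=14")

# (low, high, label) with both endpoints inclusive; adjacent bins disjoint.
_AGE_BINS = {
    Scheme.HNR: ((46, 55, "46-55"), (56, 65, "56-65"), (66, 75, "66-75"), (76, 85, "76-85")),
    Scheme.ADNI: ((46, 55, "46-55"), (56, 65, "56-65"), (66, 75, "66-75"), (76, 90, "76-90")),
}

#: Fixed ordering of the five branded variables; marker band position,
#: one-hot block order and ablation contexts all follow this order.
VARIABLE_ORDER = ("age", "gender", "education", "marital_status", "apoe4")


def age_bins(scheme: Scheme | str) -> tuple[str, ...]:
    """Ordered age-group labels for a scheme."""
    return tuple(label for _, _, label in _AGE_BINS[Scheme(scheme)])


def category_orders(scheme: Scheme | str = Scheme.HNR) -> dict[str, tuple[str, ...]]:
    """Ordered categories per variable (block sizes 4, 2, 3, 4, 2)."""
    return {
        "age": age_bins(scheme),
        "gender": GENDERS,
        "education": EDUCATION_BINS,
        "marital_status": MARITAL_STATUSES,
        "apoe4": APOE4_STATUSES,
    }


#: Category orders under the default (HNR) scheme.
CATEGORY_ORDERS = category_orders(Scheme.HNR)


def bin_age(age: int, scheme: Scheme | str = Scheme.HNR, clamp: bool = False) -> str:
    """Map an integer age in years to its age group.

    Ages outside the scheme's range raise :class:`CohortError` unless
    ``clamp`` is set, in which case they map to the nearest extreme bin.
    """
    age = int(age)
    bins = _AGE_BINS[Scheme(scheme)]
    for low, high, label in bins:
        if low <= age <= high:
            return label
    if clamp:
        return bins[0][2] if age < bins[0][0] else bins[-1][2]
    raise CohortError(
        f"age {age} outside the {Scheme(scheme).value} range "
        f"[{bins[0][0]}, {bins[-1][1]}]"
    )


def bin_education(years: int) -> str:
    """Map years of formal education to one of three groups."""
    years = int(years)
    if years < 0:
        raise CohortError(f"education years must be non-negative, got {years}")
    if years <= 10:
        return "<=10"
    if years <= 13:
        return "11-13"
    return ">=14"


@dataclass(frozen=True)
class ParticipantRecord:
    """Raw covariates and diagnosis label for one participant."""

    participant_id: str
    age: int
    gender: str
    education_years: int
    marital_status: str
    apoe4: str
    label: str

    def __post_init__(self) -> None:
        for field, value, allowed in (
            ("gender", self.gender, GENDERS),
            ("marital_status", self.marital_status, MARITAL_STATUSES),
            ("apoe4", self.apoe4, APOE4_STATUSES),
            ("label", self.label, LABELS),
        ):
            if value not in allowed:
                raise CohortError(
                    f"participant {self.participant_id!r}: invalid {field} "
                    f"{value!r}; expected one of {allowed}"
                )
        if int(self.education_years) < 0:
            raise CohortError(
                f"participant {self.participant_id!r}: negative education years"
            )


@dataclass(frozen=True)
class BinnedMetadata:
    """The five binned covariates for one participant.

    Category counts per variable are 4 (age), 2 (gender), 3 (education),
    4 (marital status), 2 (APOE-ε4): 15 categories in total.
    """

    age_group: str
    gender: str
    education_group: str
    marital_status: str
    apoe4: str

    def as_dict(self) -> dict[str, str]:
        return {
            "age": self.age_group,
            "gender": self.gender,
            "education": self.education_group,
            "marital_status": self.marital_status,
            "apoe4": self.apoe4,
        }


def bin_record(
    record: ParticipantRecord,
    scheme: Scheme | str = Scheme.HNR,
    clamp_age: bool = False,
) -> BinnedMetadata:
    """Bin a participant record's covariates; categoricals pass through."""
    return BinnedMetadata(
        age_group=bin_age(record.age, scheme, clamp=clamp_age),
        gender=record.gender,
        education_group=bin_education(record.education_years),
        marital_status=record.marital_status,
        apoe4=record.apoe4,
    )


_CSV_COLUMNS = (
    "participant_id",
    "age",
    "gender",
    "education_years",
    "marital_status",
    "apoe4",
    "label",
)


@dataclass(frozen=True)
class CohortTable:
    """Ordered collection of participant records plus the age scheme."""

    records: tuple[ParticipantRecord, ...]
    scheme: Scheme = Scheme.HNR

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.participant_id for r in self.records)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.records)

    def class_counts(self) -> dict[str, int]:
        labels = self.labels
        return {lab: labels.count(lab) for lab in LABELS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "participant_id": r.participant_id,
                    "age": r.age,
                    "gender": r.gender,
                    "education_years": r.education_years,
                    "marital_status": r.marital_status,
                    "apoe4": r.apoe4,
                    "label": r.label,
                }
                for r in self.records
            ],
            columns=list(_CSV_COLUMNS),
        )


def read_cohort_table(path: str | Path, scheme: Scheme | str = Scheme.HNR) -> CohortTable:
    """Read a covariate CSV into a :class:`CohortTable`.

    The file must carry the header
    ``participant_id,age,gender,education_years,marital_status,apoe4,label``.
    Errors name the offending row (1-based, excluding the header).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"{path}: empty cohort file") from exc
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")
    if len(frame) == 0:
        raise CohortError(f"{path}: no data rows")

    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                ParticipantRecord(
                    participant_id=str(row.participant_id),
                    age=_parse_int(row.age, "age"),
                    gender=str(row.gender),
                    education_years=_parse_int(row.education_years, "education_years"),
                    marital_status=str(row.marital_status),
                    apoe4=str(row.apoe4),
                    label=str(row.label),
                )
            )
        except CohortError as exc:
            raise CohortError(f"{path}: row {row_number}: {exc}") from exc
    return CohortTable(records=tuple(records), scheme=Scheme(scheme))


def _parse_int(value, field: str) -> int:
    try:
        return int(str(value))
    except (TypeError, ValueError) as exc:
        raise CohortError(f"unparseable {field} value {value!r}") from exc


def write_cohort_table(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort to CSV; inverse of :func:`read_cohort_table`."""
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    return path
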