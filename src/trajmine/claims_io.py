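"""Reading, validating and normalising stay-level hospital claim records.

One row of input is one hospitalization: an anonymous patient identifier,
the admitting hospital, admission date, length of stay, discharge status,
demographics, the coded diagnoses (ICD-10: one principal, an optional
related diagnosis giving the aetiology, and any number of comorbidities),
the coded procedures (CCAM-style), and the stay cost.

Diagnosis codes are coarsened before analysis: keeping only the first three
characters of an ICD-10 code groups clinically close variants ("C504" and
"C509" both become "C50"), except for chapter-XXI Z-codes, where the fourth
and fifth characters carry information about the type of contact with the
health system (chemotherapy session Z511 vs radiotherapy session Z510) and
are retained.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from datetime import date

logger = logging.getLogger(__name__)

#: Canonical column order of the delimited claims format.
CANONICAL_COLUMNS = [
    "patient_id",
    "hospital_id",
    "stay_index",
    "age",
    "gender",
    "admission_date",
    "stay_duration",
    "discharge_status",
    "drg",
    "principal_dx",
    "related_dx",
    "comorbidity_dx",
    "procedures",
    "cost",
    "is_radiotherapy_session",
]

_MANDATORY_COLUMNS = [c for c in CANONICAL_COLUMNS if c not in ("drg", "related_dx")]

_ICD10_SHAPE = re.compile(r"^[A-Z][0-9]{2}")

_GENDERS = {"F", "M", "unknown"}
_DISCHARGE_STATUSES = {"home", "transfer", "death", "other"}


@dataclass(frozen=True)
class StayRecord:
    """A single hospitalization claim line."""

    patient_id: str
    hospital_id: str
    stay_index: str
    age: int
    gender: str
    admission_date: date
    stay_duration: int
    discharge_status: str
    principal_dx: str
    related_dx: str | None = None
    comorbidity_dx: tuple[str, ...] = ()
    procedures: tuple[str, ...] = ()
    cost: float = 0.0
    drg: str | None = None
    is_radiotherapy_session: bool = False

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not _ICD10_SHAPE.match(self.principal_dx or ""):
            raise ValueError(
                f"principal_dx {self.principal_dx!r} does not look like an ICD-10 code"
            )
        if self.gender not in _GENDERS:
            raise ValueError(f"gender must be one of {sorted(_GENDERS)}")
        if self.discharge_status not in _DISCHARGE_STATUSES:
            raise ValueError(
                f"discharge_status must be one of {sorted(_DISCHARGE_STATUSES)}"
            )
        if self.stay_duration < 0:
            raise ValueError("stay_duration must be >= 0")
        if self.cost < 0:
            raise ValueError("cost must be >= 0")
        if not 0 <= self.age <= 130:
            raise ValueError("age must be between 0 and 130")

    def all_diagnoses(self) -> tuple[str, ...]:
        """Principal, related (if any) and comorbidity codes, in that order."""
        dx = [self.principal_dx]
        if self.related_dx:
            dx.append(self.related_dx)
        dx.extend(self.comorbidity_dx)
        return tuple(dx)


@dataclass(frozen=True)
class CodeGranularityPolicy:
    """How many characters of an ICD-10 code to retain as an attribute.

    ``default_length`` characters are kept (3 groups codes at the
    category level); prefixes listed in ``exceptions`` keep a longer
    stem, by default chapter-XXI Z-codes keep up to 5 characters.
    """

    default_length: int = 3
    exceptions: dict[str, int] = field(default_factory=lambda: {"Z": 5})

    def __post_init__(self) -> None:
        lengths = [self.default_length, *self.exceptions.values()]
        if any(not 3 <= n <= 7 for n in lengths):
            raise ValueError("retained code lengths must be between 3 and 7")


def normalize_code(code: str) -> str:
    """Uppercase an ICD-10 code and strip dots ("C50.4" -> "C504")."""
    return code.strip().upper().replace(".", "")


def truncate_code(code: str, policy: CodeGranularityPolicy | None = None) -> str:
    """Coarsen an ICD-10 code according to the granularity policy.

    >>> truncate_code("C504")
    'C50'
    >>> truncate_code("Z511")
    'Z511'
    """
    if policy is None:
        policy = CodeGranularityPolicy()
    code = normalize_code(code)
    if not code:
        raise ValueError("cannot truncate an empty code")
    length = policy.default_length
    for prefix, kept in policy.exceptions.items():
        if code.startswith(prefix):
            length = max(length, kept)
            break
    return code[:length]


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str


def _parse_bool(text: str) -> bool:
    text = text.strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("", "0", "false", "no"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _parse_row(row: dict[str, str]) -> StayRecord:
    related = normalize_code(row.get("related_dx") or "")
    comorbid = tuple(
        normalize_code(c) for c in (row.get("comorbidity_dx") or "").split(";") if c.strip()
    )
    procedures = tuple(
        p.strip().upper() for p in (row.get("procedures") or "").split(";") if p.strip()
    )
    return StayRecord(
        patient_id=row["patient_id"].strip(),
        hospital_id=row["hospital_id"].strip(),
        stay_index=row["stay_index"].strip(),
        age=int(row["age"]),
        gender=row["gender"].strip(),
        admission_date=date.fromisoformat(row["admission_date"].strip()),
        stay_duration=int(row["stay_duration"]),
        discharge_status=row["discharge_status"].strip(),
        drg=(row.get("drg") or "").strip() or None,
        principal_dx=normalize_code(row["principal_dx"]),
        related_dx=related or None,
        comorbidity_dx=comorbid,
        procedures=procedures,
        cost=float(row["cost"]),
        is_radiotherapy_session=_parse_bool(row.get("is_radiotherapy_session", "")),
    )


def read_claims(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str = ",",
    rejected: list[RejectedRow] | None = None,
) -> list[StayRecord]:
    """Read stay records from a delimited text file.

    ``column_map`` maps canonical field names to header names in the file
    (identity by default). Rows that fail to parse or validate are skipped
    and logged with their line number; pass a list as ``rejected`` to
    collect them. A missing mandatory column raises immediately.
    """
    column_map = column_map or {}
    records: list[StayRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        header = reader.fieldnames or []
        for canonical in _MANDATORY_COLUMNS:
            source = column_map.get(canonical, canonical)
            if source not in header:
                raise ValueError(f"missing mandatory column: {source!r}")
        for row in reader:
            mapped = {
                canonical: row.get(column_map.get(canonical, canonical), "")
                for canonical in CANONICAL_COLUMNS
            }
            try:
                records.append(_parse_row(mapped))
            except (ValueError, KeyError) as exc:
                line = reader.line_num
                logger.warning("rejected claim row at line %d: %s", line, exc)
                if rejected is not None:
                    rejected.append(RejectedRow(line, str(exc)))
    return records


def write_claims(records: list[StayRecord], path, delimiter: str = ",") -> None:
    """Write records in the canonical delimited format (inverse of read_claims)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(CANONICAL_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.hospital_id,
                    rec.stay_index,
                    rec.age,
                    rec.gender,
                    rec.admission_date.isoformat(),
                    rec.stay_duration,
                    rec.discharge_status,
                    rec.drg or "",
                    rec.principal_dx,
                    rec.related_dx or "",
                    ";".join(rec.comorbidity_dx),
                    ";".join(rec.procedures),
                    repr(rec.cost),
                    int(rec.is_radiotherapy_session),
                ]
            )


def with_death_on_last_stay(records: list[StayRecord]) -> list[StayRecord]:
    """Validate that a death discharge only occurs on a patient's last stay.

    Returns the records unchanged; raises if some patient has a stay after
    a stay discharged as death.
    """
    last_seen: dict[str, date] = {}
    death_date: dict[str, date] = {}
    for rec in records:
        if rec.discharge_status == "death":
            death_date[rec.patient_id] = rec.admission_date
        prev = last_seen.get(rec.patient_id)
        if prev is None or rec.admission_date > prev:
            last_seen[rec.patient_id] = rec.admission_date
    for pid, when in death_date.items():
        if last_seen[pid] > when:
            raise ValueError(f"patient {pid} has a stay after a death discharge")
    return records


__all__ = [
    "CANONICAL_COLUMNS",
    "StayRecord",
    "CodeGranularityPolicy",
    "RejectedRow",
    "normalize_code",
    "truncate_code",
    "read_claims",
    "write_claims",
    "with_death_on_last_stay",
]
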