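"""Index-stay selection and one-year trajectory-of-care assembly.

A trajectory of care anchors on an *index stay* — the first hospitalization
of the target year combining a qualifying diagnosis (by default breast
cancer, C50*/D05*) with a surgical procedure — and collects every
subsequent stay of the same patient beginning strictly less than
``window_days`` (default 366) after it, whatever the reason for admission.
Patients with a similar qualifying stay in the lookback period before their
index stay are treated as prevalent cases and excluded, so the cohort
approximates incident surgical cases. Ambulatory radiotherapy sessions are
removed because they are inconsistently recorded across facility types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from trajmine.claims_io import CodeGranularityPolicy, StayRecord, truncate_code

logger = logging.getLogger(__name__)

#: truncated principal diagnosis identifying a chemotherapy session stay
DEFAULT_CHEMO_CODE = "Z511"


@dataclass(frozen=True)
class SelectionRule:
    """Cohort-entry rule: which stays qualify as surgical index candidates."""

    dx_prefixes: frozenset[str] = frozenset({"C50", "D05"})
    surgery_procedures: frozenset[str] = frozenset({"QEFA", "QEHA", "QECA"})
    target_year: int = 2009
    lookback_days: int = 365
    window_days: int = 366
    calendar_lookback: bool = False
    chemo_code: str = DEFAULT_CHEMO_CODE

    def __post_init__(self) -> None:
        if not self.dx_prefixes or not self.surgery_procedures:
            raise ValueError("dx_prefixes and surgery_procedures must be non-empty")
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")


@dataclass(frozen=True)
class TrajectoryIndicators:
    """Per-trajectory utilisation and outcome summary."""

    total_cost: float
    n_stays: int
    cum_length_of_stay: int
    n_chemo_sessions: int
    chemo_cost: float
    died: bool
    age: int
    gender: str


@dataclass(frozen=True)
class Trajectory:
    patient_id: str
    index_stay: StayRecord
    stays: tuple[StayRecord, ...]
    indicators: TrajectoryIndicators


@dataclass(frozen=True)
class RejectedPatient:
    patient_id: str
    reason: str  # "prevalent" or "no_candidate"


def _qualifying(stay: StayRecord, rule: SelectionRule) -> bool:
    """Diagnosis/procedure co-occurrence, regardless of year."""
    has_dx = any(
        dx.startswith(prefix) for dx in stay.all_diagnoses() for prefix in rule.dx_prefixes
    )
    has_surgery = any(
        proc.startswith(prefix)
        for proc in stay.procedures
        for prefix in rule.surgery_procedures
    )
    return has_dx and has_surgery


def is_index_candidate(stay: StayRecord, rule: SelectionRule) -> bool:
    """True iff the stay qualifies and is admitted in the target year."""
    return stay.admission_date.year == rule.target_year and _qualifying(stay, rule)


def _sort_key(stay: StayRecord):
    return (stay.admission_date, stay.stay_index)


def select_index_stays(
    records: list[StayRecord],
    rule: SelectionRule,
    rejected: list[RejectedPatient] | None = None,
) -> dict[str, StayRecord]:
    """Pick each patient's index stay, excluding prevalent cases.

    For every patient with at least one candidate stay in the target year,
    the chronologically first candidate is the index (ties on admission
    date broken by the smaller stay_index, with a warning). Patients with
    a qualifying stay in the lookback period strictly before their index
    are prevalent cases: excluded and reported with reason ``prevalent``.
    Patients with no target-year candidate are reported ``no_candidate``.
    """
    by_patient: dict[str, list[StayRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    selected: dict[str, StayRecord] = {}
    for pid, stays in by_patient.items():
        candidates = sorted((s for s in stays if is_index_candidate(s, rule)), key=_sort_key)
        if not candidates:
            if rejected is not None:
                rejected.append(RejectedPatient(pid, "no_candidate"))
            continue
        index = candidates[0]
        if len(candidates) > 1 and candidates[1].admission_date == index.admission_date:
            logger.warning(
                "patient %s has two candidate stays on %s; keeping stay_index %s",
                pid,
                index.admission_date,
                index.stay_index,
            )
        prevalent = False
        for stay in stays:
            if not _qualifying(stay, rule):
                continue
            if rule.calendar_lookback:
                prevalent = stay.admission_date.year == rule.target_year - 1
            else:
                delta = (index.admission_date - stay.admission_date).days
                prevalent = 0 < delta <= rule.lookback_days
            if prevalent:
                break
        if prevalent:
            if rejected is not None:
                rejected.append(RejectedPatient(pid, "prevalent"))
            continue
        selected[pid] = index
    return selected


def build_trajectory(
    patient_records: list[StayRecord],
    index: StayRecord,
    rule: SelectionRule,
    policy: CodeGranularityPolicy | None = None,
) -> Trajectory:
    """Assemble the one-year trajectory anchored on the index stay.

    Keeps every stay of the patient starting 0 <= d < window_days days
    after the index admission, drops radiotherapy sessions, sorts by
    admission date (ties by stay_index), and computes the indicators.
    """
    if index not in patient_records:
        raise ValueError("index stay does not belong to the patient's records")
    followups = sorted(
        (
            s
            for s in patient_records
            if s != index
            and not s.is_radiotherapy_session
            and 0 <= (s.admission_date - index.admission_date).days < rule.window_days
        ),
        key=_sort_key,
    )
    stays = [index, *followups]
    indicators = compute_indicators(stays, chemo_code=rule.chemo_code, policy=policy)
    return Trajectory(
        patient_id=index.patient_id,
        index_stay=index,
        stays=tuple(stays),
        indicators=indicators,
    )


def compute_indicators(
    stays: list[StayRecord] | tuple[StayRecord, ...],
    chemo_code: str = DEFAULT_CHEMO_CODE,
    policy: CodeGranularityPolicy | None = None,
) -> TrajectoryIndicators:
    """Summarise an ordered stay list into trajectory indicators.

    A chemotherapy session is a stay whose truncated principal diagnosis
    equals ``chemo_code``. Death is detected from the discharge status of
    any stay (in-hospital deaths only).
    """
    if not stays:
        raise ValueError("cannot compute indicators for an empty trajectory")
    policy = policy or CodeGranularityPolicy()
    chemo = [s for s in stays if truncate_code(s.principal_dx, policy) == chemo_code]
    index = stays[0]
    return TrajectoryIndicators(
        total_cost=sum(s.cost for s in stays),
        n_stays=len(stays),
        cum_length_of_stay=sum(s.stay_duration for s in stays),
        n_chemo_sessions=len(chemo),
        chemo_cost=sum(s.cost for s in chemo),
        died=any(s.discharge_status == "death" for s in stays),
        age=index.age,
        gender=index.gender,
    )


def build_cohort(
    records: list[StayRecord],
    rule: SelectionRule,
    policy: CodeGranularityPolicy | None = None,
    rejected: list[RejectedPatient] | None = None,
) -> list[Trajectory]:
    """Full selection pipeline: index stays, then one trajectory per patient."""
    by_patient: dict[str, list[StayRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    selected = select_index_stays(records, rule, rejected=rejected)
    return [
        build_trajectory(by_patient[pid], index, rule, policy=policy)
        for pid, index in sorted(selected.items())
    ]


__all__ = [
    "DEFAULT_CHEMO_CODE",
    "SelectionRule",
    "Trajectory",
    "TrajectoryIndicators",
    "RejectedPatient",
    "is_index_candidate",
    "select_index_stays",
    "build_trajectory",
    "compute_indicators",
    "build_cohort",
]
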