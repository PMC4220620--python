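"""Trajectory formal context and per-profile summary statistics.

The diagnosis codes borne by each trajectory — principal and related
diagnoses only, coarsened by the granularity policy — become the attributes
of a formal context with patients as objects. After lattice mining and
filtering, each kept concept is a morbidity profile and its extent a
patient group; this module computes the per-profile cost and utilisation
summary (mean trajectory cost, stays, cumulative length of stay,
chemotherapy sessions and their cost, death rate, gender mix, age).

Because a patient belongs to the extent of every superconcept of their own
profile, the groups overlap: a patient in (C50, Z511) also counts in (C50)
and in the top (empty-intent) concept, which summarises the whole cohort
and serves as a baseline row.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from trajmine.claims_io import CodeGranularityPolicy, truncate_code
from trajmine.fca import FormalConcept, FormalContext
from trajmine.trajectory import Trajectory, TrajectoryIndicators


@dataclass(frozen=True)
class ConceptProfileStats:
    """Summary of the trajectories of one concept's extent."""

    intent: tuple[str, ...]
    n_patients: int
    mean_cost: float
    mean_stays: float
    mean_cum_los: float
    mean_chemo_sessions: float
    mean_chemo_cost: float
    death_rate: float
    pct_female: float
    mean_age: float


def context_from_trajectories(
    trajectories: list[Trajectory],
    policy: CodeGranularityPolicy | None = None,
    include_comorbidities: bool = False,
) -> FormalContext:
    """Patients × coarsened diagnosis codes incidence.

    An attribute is set for a patient when any stay of their trajectory
    carries the code as principal or related diagnosis (comorbidity codes
    are excluded unless ``include_comorbidities``).
    """
    if not trajectories:
        raise ValueError("no trajectories to build a context from")
    policy = policy or CodeGranularityPolicy()
    descriptions: dict[str, set[str]] = {}
    for traj in trajectories:
        if traj.patient_id in descriptions:
            raise ValueError(f"duplicate patient id: {traj.patient_id}")
        codes: set[str] = set()
        for stay in traj.stays:
            codes.add(truncate_code(stay.principal_dx, policy))
            if stay.related_dx:
                codes.add(truncate_code(stay.related_dx, policy))
            if include_comorbidities:
                codes.update(truncate_code(c, policy) for c in stay.comorbidity_dx)
        descriptions[traj.patient_id] = codes
    objects = [t.patient_id for t in trajectories]
    attributes = sorted({m for codes in descriptions.values() for m in codes})
    pairs = [(g, m) for g, codes in descriptions.items() for m in codes]
    return FormalContext(objects, attributes, pairs)


def concept_summary(
    concept: FormalConcept,
    indicators: dict[str, TrajectoryIndicators],
) -> ConceptProfileStats:
    """Means and rates over the patients of the concept's extent."""
    if not concept.extent:
        raise ValueError("cannot summarise a concept with an empty extent")
    rows = []
    for pid in concept.extent:
        try:
            rows.append(indicators[pid])
        except KeyError:
            raise ValueError(f"no indicators for extent patient {pid!r}") from None
    n = len(rows)
    return ConceptProfileStats(
        intent=concept.intent,
        n_patients=n,
        mean_cost=sum(r.total_cost for r in rows) / n,
        mean_stays=sum(r.n_stays for r in rows) / n,
        mean_cum_los=sum(r.cum_length_of_stay for r in rows) / n,
        mean_chemo_sessions=sum(r.n_chemo_sessions for r in rows) / n,
        mean_chemo_cost=sum(r.chemo_cost for r in rows) / n,
        death_rate=sum(r.died for r in rows) / n,
        pct_female=sum(r.gender == "F" for r in rows) / n,
        mean_age=sum(r.age for r in rows) / n,
    )


def render_intent(intent: tuple[str, ...]) -> str:
    return ", ".join(intent) if intent else "∅"


def stats_table(
    concepts: list[FormalConcept],
    indicators: dict[str, TrajectoryIndicators],
) -> pd.DataFrame:
    """One summary row per (filtered) concept, sorted by mean cost ascending.

    Columns: intent, n, cost, stays_n, stays_cum_length, chemo_n,
    chemo_cost, death_rate, age, pct_female. Rates are stored as
    fractions at full precision.
    """
    rows = []
    for concept in concepts:
        s = concept_summary(concept, indicators)
        rows.append(
            {
                "intent": render_intent(s.intent),
                "n": s.n_patients,
                "cost": s.mean_cost,
                "stays_n": s.mean_stays,
                "stays_cum_length": s.mean_cum_los,
                "chemo_n": s.mean_chemo_sessions,
                "chemo_cost": s.mean_chemo_cost,
                "death_rate": s.death_rate,
                "age": s.mean_age,
                "pct_female": s.pct_female,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "intent",
            "n",
            "cost",
            "stays_n",
            "stays_cum_length",
            "chemo_n",
            "chemo_cost",
            "death_rate",
            "age",
            "pct_female",
        ],
    )
    return frame.sort_values("cost", kind="mergesort").reset_index(drop=True)


__all__ = [
    "ConceptProfileStats",
    "context_from_trajectories",
    "concept_summary",
    "stats_table",
    "render_intent",
]
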