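"""Synthetic claims cohorts with planted morbidity profiles.

National claims extracts are not redistributable, so this module generates
stay-level claim records that exercise every pipeline stage: each patient
is assigned a latent morbidity profile (a set of ICD-10 codes with
profile-specific stay counts, costs, chemotherapy-session counts, death
probability and demographics), receives an index surgical stay in the
target year and follow-up stays within one year, and the cohort is salted
with the distractors the selection filters must reject — prevalent cases
(a qualifying surgical stay in the prior year), ambulatory radiotherapy
sessions, and random noise codes.

The generator guarantees that a patient's trajectory carries exactly the
profile's codes (plus at most one noise code), so the planted profiles are
recoverable as concept intents, and it emits a ground-truth table with each
patient's profile and realized indicator values so tests never have to
re-derive the truth from the generated claims.

Distributional choices: extra stay counts are Poisson, per-stay costs are
log-normal (median/σ parameterisation), ages are truncated normal, stay
durations Poisson. Chemotherapy-session stays are day cases (duration 0);
a profile whose code set contains a chemotherapy code receives at least
one session stay so its full code set is always expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from trajmine.claims_io import CodeGranularityPolicy, StayRecord, truncate_code

#: surgical procedure codes stamped on index (and prevalent) stays
SURGERY_CODES = ("QEFA004", "QEFA019", "QEHA001")
#: principal diagnoses used for injected noise stays
NOISE_CODES = ("R073", "K529", "J189", "M545", "N390", "E119")
NOISE_COST_MEDIAN = 300.0
NOISE_COST_SIGMA = 0.4
RADIOTHERAPY_CODE = "Z5101"
HOSPITALS = ("H001", "H002", "H003", "H004", "H005")

_CHEMO_PREFIX = "Z511"
_ANCHOR_PREFIXES = ("C50", "D05")


@dataclass(frozen=True)
class ProfileSpec:
    """One latent morbidity profile and its generating parameters."""

    name: str
    codes: tuple[str, ...]  # full-length ICD-10 codes, pre-truncation
    prevalence: float
    n_extra_stays: float  # Poisson mean of additional follow-up stays
    n_chemo_sessions: float  # mean chemotherapy-session count (0 allowed)
    cost_median: float  # log-normal median of the per-stay cost (€)
    cost_sigma: float  # log-normal σ
    p_death: float
    age_mean: float
    age_sd: float
    p_female: float
    mean_los: float = 4.0  # Poisson mean stay duration (days); sessions are 0

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"profile {self.name!r} has an empty code set")
        if self.anchor_code is None:
            raise ValueError(
                f"profile {self.name!r} needs a C50*/D05* code to anchor the index stay"
            )
        for p in (self.prevalence, self.p_death, self.p_female):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cost_sigma <= 0 or self.cost_median <= 0:
            raise ValueError("cost scale parameters must be positive")

    @property
    def anchor_code(self) -> str | None:
        for code in sorted(self.codes):
            if code.startswith(_ANCHOR_PREFIXES):
                return code
        return None

    @property
    def chemo_codes(self) -> tuple[str, ...]:
        return tuple(c for c in sorted(self.codes) if c.startswith(_CHEMO_PREFIX))

    @property
    def coverage_codes(self) -> tuple[str, ...]:
        """Codes expressed by one dedicated follow-up stay each."""
        anchor = self.anchor_code
        return tuple(
            c
            for c in sorted(self.codes)
            if c != anchor and not c.startswith(_CHEMO_PREFIX)
        )

    def truncated_codes(self, policy: CodeGranularityPolicy | None = None) -> frozenset[str]:
        policy = policy or CodeGranularityPolicy()
        return frozenset(truncate_code(c, policy) for c in self.codes)

    def expected_n_chemo(self) -> float:
        if not self.chemo_codes or self.n_chemo_sessions <= 0:
            return 0.0
        return 1.0 + max(self.n_chemo_sessions - 1.0, 0.0)

    def expected_n_stays(self) -> float:
        return 1.0 + len(self.coverage_codes) + self.expected_n_chemo() + self.n_extra_stays

    def mean_stay_cost(self) -> float:
        return self.cost_median * math.exp(self.cost_sigma**2 / 2)

    def expected_total_cost(self) -> float:
        return self.expected_n_stays() * self.mean_stay_cost()

    def expected_chemo_cost(self) -> float:
        return self.expected_n_chemo() * self.mean_stay_cost()

    def expected_cum_los(self) -> float:
        return (self.expected_n_stays() - self.expected_n_chemo()) * self.mean_los


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int
    profiles: tuple[ProfileSpec, ...]
    target_year: int = 2009
    noise_code_rate: float = 0.0  # per-patient chance of one extra random code
    p_prevalent_distractor: float = 0.0
    p_radiotherapy_stays: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        total = sum(p.prevalence for p in self.profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile prevalences must sum to 1 (got {total})")
        for rate in (
            self.noise_code_rate,
            self.p_prevalent_distractor,
            self.p_radiotherapy_stays,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class _StayPlan:
    day: int  # days after index admission (0 = index)
    principal: str
    related: str | None
    cost: float
    duration: int
    is_chemo: bool
    procedures: tuple[str, ...] = ()


def _draw_cost(rng: np.random.Generator, median: float, sigma: float) -> float:
    return round(float(median * math.exp(sigma * rng.standard_normal())), 2)


def generate_cohort(cfg: CohortConfig) -> tuple[list[StayRecord], pd.DataFrame]:
    """Generate claim records and the ground-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per patient:
    patient_id, profile, is_prevalent, n_radio_stays plus the realized
    trajectory indicators (total_cost, n_stays, cum_length_of_stay,
    n_chemo_sessions, chemo_cost, died, age, gender) computed directly
    from the planted stays. The whole output is reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    profiles = cfg.profiles
    prevalences = np.array([p.prevalence for p in profiles])
    prevalences = prevalences / prevalences.sum()
    year_start = date(cfg.target_year, 1, 1)
    records: list[StayRecord] = []
    truth_rows: list[dict] = []
    stay_counter = 0

    def next_stay_index() -> str:
        nonlocal stay_counter
        stay_counter += 1
        return f"S{stay_counter:07d}"

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:06d}"
        profile = profiles[int(rng.choice(len(profiles), p=prevalences))]
        age = int(np.clip(round(rng.normal(profile.age_mean, profile.age_sd)), 18, 99))
        gender = "F" if rng.random() < profile.p_female else "M"
        hospital = str(rng.choice(HOSPITALS))
        index_day_of_year = int(rng.integers(0, 365))
        index_date = year_start + timedelta(days=index_day_of_year)

        plans: list[_StayPlan] = [
            _StayPlan(
                day=0,
                principal=profile.anchor_code,
                related=None,
                cost=_draw_cost(rng, profile.cost_median, profile.cost_sigma),
                duration=int(rng.poisson(profile.mean_los)),
                is_chemo=False,
                procedures=(str(rng.choice(SURGERY_CODES)),),
            )
        ]
        for code in profile.coverage_codes:
            plans.append(
                _StayPlan(
                    day=int(rng.integers(1, 366)),
                    principal=code,
                    related=profile.anchor_code if rng.random() < 0.5 else None,
                    cost=_draw_cost(rng, profile.cost_median, profile.cost_sigma),
                    duration=int(rng.poisson(profile.mean_los)),
                    is_chemo=False,
                )
            )
        n_chemo = 0
        if profile.chemo_codes and profile.n_chemo_sessions > 0:
            n_chemo = 1 + int(rng.poisson(max(profile.n_chemo_sessions - 1.0, 0.0)))
            chemo_code = profile.chemo_codes[0]
            for _ in range(n_chemo):
                plans.append(
                    _StayPlan(
                        day=int(rng.integers(1, 366)),
                        principal=chemo_code,
                        related=profile.anchor_code,
                        cost=_draw_cost(rng, profile.cost_median, profile.cost_sigma),
                        duration=0,
                        is_chemo=True,
                    )
                )
        non_chemo_codes = [profile.anchor_code, *profile.coverage_codes]
        for _ in range(int(rng.poisson(profile.n_extra_stays))):
            plans.append(
                _StayPlan(
                    day=int(rng.integers(1, 366)),
                    principal=str(rng.choice(non_chemo_codes)),
                    related=None,
                    cost=_draw_cost(rng, profile.cost_median, profile.cost_sigma),
                    duration=int(rng.poisson(profile.mean_los)),
                    is_chemo=False,
                )
            )
        if rng.random() < cfg.noise_code_rate:
            plans.append(
                _StayPlan(
                    day=int(rng.integers(1, 366)),
                    principal=str(rng.choice(NOISE_CODES)),
                    related=None,
                    cost=_draw_cost(rng, NOISE_COST_MEDIAN, NOISE_COST_SIGMA),
                    duration=int(rng.poisson(2.0)),
                    is_chemo=False,
                )
            )

        died = bool(rng.random() < profile.p_death)
        death_day = None
        if died:
            death_day = max(p.day for p in plans)

        # radiotherapy sessions: flagged, must be filtered out downstream;
        # never placed after an in-hospital death
        n_radio = 0
        if rng.random() < cfg.p_radiotherapy_stays:
            n_radio = 1 + int(rng.poisson(3.0))
            radio_days = []
            limit = death_day if death_day is not None else 366
            if limit > 1:
                radio_days = [int(d) for d in rng.integers(1, limit, size=n_radio)]
            n_radio = len(radio_days)
        else:
            radio_days = []

        is_prevalent = bool(rng.random() < cfg.p_prevalent_distractor)

        # emit the trajectory stays
        plans.sort(key=lambda p: p.day)
        last_day = plans[-1].day
        for plan in plans:
            records.append(
                StayRecord(
                    patient_id=pid,
                    hospital_id=hospital,
                    stay_index=next_stay_index(),
                    age=age,
                    gender=gender,
                    admission_date=index_date + timedelta(days=plan.day),
                    stay_duration=plan.duration,
                    discharge_status="death" if died and plan.day == last_day and plan is plans[-1] else "home",
                    drg="09C05",
                    principal_dx=plan.principal,
                    related_dx=plan.related,
                    comorbidity_dx=("I10",) if rng.random() < 0.2 else (),
                    procedures=plan.procedures,
                    cost=plan.cost,
                    is_radiotherapy_session=False,
                )
            )
        for day in radio_days:
            records.append(
                StayRecord(
                    patient_id=pid,
                    hospital_id=hospital,
                    stay_index=next_stay_index(),
                    age=age,
                    gender=gender,
                    admission_date=index_date + timedelta(days=day),
                    stay_duration=0,
                    discharge_status="home",
                    drg="28Z11",
                    principal_dx=RADIOTHERAPY_CODE,
                    related_dx=profile.anchor_code,
                    cost=_draw_cost(rng, 200.0, 0.3),
                    is_radiotherapy_session=True,
                )
            )
        if is_prevalent:
            # qualifying surgical stay in the prior calendar year, within a
            # 365-day rolling lookback of the index admission
            doy = index_day_of_year + 1
            delta = int(rng.integers(doy, 366))
            records.append(
                StayRecord(
                    patient_id=pid,
                    hospital_id=hospital,
                    stay_index=next_stay_index(),
                    age=age,
                    gender=gender,
                    admission_date=index_date - timedelta(days=delta),
                    stay_duration=int(rng.poisson(profile.mean_los)),
                    discharge_status="home",
                    drg="09C05",
                    principal_dx=profile.anchor_code,
                    related_dx=None,
                    procedures=(str(rng.choice(SURGERY_CODES)),),
                    cost=_draw_cost(rng, profile.cost_median, profile.cost_sigma),
                    is_radiotherapy_session=False,
                )
            )

        truth_rows.append(
            {
                "patient_id": pid,
                "profile": profile.name,
                "is_prevalent": is_prevalent,
                "n_radio_stays": len(radio_days),
                "total_cost": round(sum(p.cost for p in plans), 2),
                "n_stays": len(plans),
                "cum_length_of_stay": sum(p.duration for p in plans),
                "n_chemo_sessions": n_chemo,
                "chemo_cost": round(sum(p.cost for p in plans if p.is_chemo), 2),
                "died": died,
                "age": age,
                "gender": gender,
            }
        )

    return records, pd.DataFrame(truth_rows)


def default_study_config(
    n_patients: int = 5000, seed: int = 0, **overrides
) -> CohortConfig:
    """A ten-profile breast-surgery cohort with realistic contrasts.

    Profiles range from in-situ carcinoma alone (few, cheap stays, almost
    no deaths) through invasive cancer with chemotherapy courses
    (many session stays, intermediate-high costs) up to a palliative-care
    profile with the highest cost, longest stays and highest death rate.
    Costs per stay are log-normal; each profile's expected total trajectory
    cost is the product of its expected stay count and mean stay cost,
    yielding a well-separated cost ordering across profiles.
    """
    profiles = (
        ProfileSpec("in_situ", ("D059",), 0.08, 0.9, 0.0, 3400.0, 0.4, 0.002, 57.6, 10.0, 0.99),
        ProfileSpec("invasive", ("C502",), 0.29, 1.0, 0.0, 4600.0, 0.4, 0.01, 60.6, 11.0, 0.99),
        ProfileSpec("chemo_device", ("C504", "Z452", "Z511"), 0.15, 0.3, 8.0, 1650.0, 0.4, 0.01, 56.1, 10.0, 0.99),
        ProfileSpec("chemo", ("C504", "Z511"), 0.25, 0.5, 8.0, 1850.0, 0.4, 0.01, 55.3, 10.0, 0.99),
        ProfileSpec("plastic_surgery", ("C509", "Z421"), 0.06, 1.0, 0.0, 4300.0, 0.4, 0.003, 51.2, 9.0, 1.0),
        ProfileSpec("in_situ_plastic", ("D059", "Z421"), 0.03, 1.0, 0.0, 3690.0, 0.4, 0.001, 50.4, 9.0, 1.0),
        ProfileSpec("node_metastasis", ("C508", "C770"), 0.04, 1.0, 0.0, 6600.0, 0.4, 0.02, 57.6, 10.0, 0.99),
        ProfileSpec("chemo_aplasia", ("C504", "D610", "Z511"), 0.04, 0.5, 8.0, 2100.0, 0.4, 0.03, 56.6, 10.0, 0.99),
        ProfileSpec("distant_metastasis", ("C504", "C795"), 0.03, 2.0, 0.0, 6350.0, 0.4, 0.24, 58.9, 11.0, 0.99),
        ProfileSpec("palliative", ("C509", "Z515"), 0.03, 2.5, 0.0, 6560.0, 0.4, 0.69, 65.5, 12.0, 0.99, mean_los=9.0),
    )
    cfg = CohortConfig(
        n_patients=n_patients,
        profiles=profiles,
        target_year=2009,
        noise_code_rate=0.05,
        p_prevalent_distractor=0.05,
        p_radiotherapy_stays=0.30,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# -- analytic expectations (for parameter-recovery checks) -----------------


def expected_concept_stats(
    cfg: CohortConfig,
    intent: frozenset[str] | set[str],
    policy: CodeGranularityPolicy | None = None,
) -> dict[str, float]:
    """Generating expectation of a concept's per-patient statistics.

    A concept with the given intent collects every patient whose profile's
    truncated code set contains the intent, so its generating mean is the
    prevalence-weighted mixture over those profiles. The per-patient noise
    stay (rate ``noise_code_rate``) adds its expected cost to every
    profile. Returns support_fraction (of the selected cohort), mean_cost,
    death_rate, mean_n_stays, mean_chemo_sessions.
    """
    intent = frozenset(intent)
    policy = policy or CodeGranularityPolicy()
    noise_cost = cfg.noise_code_rate * NOISE_COST_MEDIAN * math.exp(NOISE_COST_SIGMA**2 / 2)
    members = [p for p in cfg.profiles if intent <= p.truncated_codes(policy)]
    weight = sum(p.prevalence for p in members)
    if weight == 0:
        return {
            "support_fraction": 0.0,
            "mean_cost": float("nan"),
            "death_rate": float("nan"),
            "mean_n_stays": float("nan"),
            "mean_chemo_sessions": float("nan"),
        }
    mix = lambda f: sum(p.prevalence * f(p) for p in members) / weight
    return {
        "support_fraction": weight,
        "mean_cost": mix(ProfileSpec.expected_total_cost) + noise_cost,
        "death_rate": mix(lambda p: p.p_death),
        "mean_n_stays": mix(ProfileSpec.expected_n_stays) + cfg.noise_code_rate,
        "mean_chemo_sessions": mix(ProfileSpec.expected_n_chemo),
    }


def planted_intents(
    cfg: CohortConfig, policy: CodeGranularityPolicy | None = None
) -> list[frozenset[str]]:
    """The distinct truncated code sets of the planted profiles."""
    policy = policy or CodeGranularityPolicy()
    seen: list[frozenset[str]] = []
    for p in cfg.profiles:
        codes = p.truncated_codes(policy)
        if codes not in seen:
            seen.append(codes)
    return seen


__all__ = [
    "SURGERY_CODES",
    "NOISE_CODES",
    "RADIOTHERAPY_CODE",
    "ProfileSpec",
    "CohortConfig",
    "generate_cohort",
    "default_study_config",
    "expected_concept_stats",
    "planted_intents",
]
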