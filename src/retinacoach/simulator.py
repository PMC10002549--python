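"""Synthetic clinic and resident-behavior models driving a full rotation.

The simulator emulates the study conditions of a university retina clinic:
an expected 1000 patients per year arriving Poisson-fashion over 240
allocation days (months 3–12 of the rotation; the two initiation months see
no allocations), distributed over the 19 retinal conditions proportionally
to their published test-set supports, with a small out-of-scope fraction.
Ten simulated residents respond to each graded case through an OSCE
checklist model: diagnosis correctness is Bernoulli in a logistic of skill
minus case difficulty, the fraction of checked boxes is Beta-distributed
with mean increasing in skill, skill grows with each encounter and decays
with idle time.  Difficulty bands are sampled directly (the image-based
difficulty path is exercised in its own module); an integrated mode can
wire the classifier and difficulty scorer in for end-to-end smoke tests.

``run_year`` produces a SimReport: per-resident teaching files, the
resident-by-condition coverage matrix, goal-attainment timeline, and a
fairness summary of total assignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .allocation import (AllocationDecision, EngineConfig, EngineState,
                         PendingCase, run_day)
from .curation import published_class_counts
from .records import CaseRecord, compute_grade, goal_status, performance_band
from .taxonomy import (ConditionTaxonomy, default_taxonomy, difficulty_score)

__all__ = [
    "SimConfig",
    "ResidentBehavior",
    "SimReport",
    "default_condition_distribution",
    "generate_patient",
    "simulate_response",
    "run_year",
]

BANDS = ("easy", "medium", "difficult")
CHECKLIST_BOXES = 37  # size of the reference OSCE checklist


def default_condition_distribution(
    taxonomy: ConditionTaxonomy | None = None) -> Dict[str, float]:
    """Condition frequencies proportional to published test-set supports,
    collapsed to the 19 allocation-level RCs."""
    tax = taxonomy or default_taxonomy()
    counts = published_class_counts()["test"]
    weights: Dict[str, float] = {}
    for code, n in counts.items():
        rc = next(iter(tax.collapse_dr([code])))
        weights[rc] = weights.get(rc, 0.0) + float(n)
    total = sum(weights.values())
    return {rc: w / total for rc, w in sorted(weights.items())}


@dataclass
class SimConfig:
    n_residents: int = 10
    annual_patients: int = 1000
    allocation_days: int = 240
    days_per_month: int = 24
    out_of_19_prob: float = 0.05
    condition_distribution: Optional[Mapping[str, float]] = None
    difficulty_distribution: Mapping[str, float] = field(
        default_factory=lambda: {b: 1.0 / 3.0 for b in BANDS})
    daily_cap: int = 2
    supplementary_months: Tuple[int, int, int] = (5, 7, 9)
    # resident behavior
    always_correct: bool = False
    skill_mean: float = 0.5
    skill_sd: float = 0.8
    difficulty_penalty: Mapping[str, float] = field(
        default_factory=lambda: {"easy": 0.0, "medium": 0.7, "difficult": 1.4})
    learning_increment: float = 0.15
    forgetting_decay: float = 0.004  # skill lost per idle day, on encounter
    checklist_concentration: float = 25.0
    seed: int = 0

    @property
    def arrival_mean(self) -> float:
        return self.annual_patients / self.allocation_days

    def __post_init__(self):
        probs = list(self.difficulty_distribution.values())
        if not np.isclose(sum(probs), 1.0):
            raise ValueError("difficulty distribution must sum to 1")
        if self.n_residents < 1 or self.allocation_days < 1:
            raise ValueError("counts must be positive")


@dataclass
class ResidentBehavior:
    """Stochastic stand-in for a resident working through OSCE cases."""

    resident_id: str
    skill: Dict[str, float]
    config: SimConfig
    last_seen: Dict[str, int] = field(default_factory=dict)

    def p_correct(self, rc: str, band: Optional[str]) -> float:
        if self.config.always_correct:
            return 1.0
        penalty = self.config.difficulty_penalty.get(band or "easy", 0.0)
        x = 1.0 + self.skill.get(rc, 0.0) - penalty
        return float(1.0 / (1.0 + np.exp(-x)))

    def checklist_fraction(self, rc: str, rng: np.random.Generator) -> float:
        if self.config.always_correct:
            return 1.0  # 81-100 % band: completes (nearly) every box
        mean = float(np.clip(0.55 + 0.10 * self.skill.get(rc, 0.0),
                             0.05, 0.97))
        kappa = self.config.checklist_concentration
        return float(rng.beta(mean * kappa, (1.0 - mean) * kappa))

    def learn(self, rc: str, day: int) -> None:
        idle = day - self.last_seen.get(rc, day)
        decayed = self.skill.get(rc, 0.0) - self.config.forgetting_decay * idle
        self.skill[rc] = decayed + self.config.learning_increment
        self.last_seen[rc] = day


def generate_patient(day: int, config: SimConfig, rng: np.random.Generator,
                     taxonomy: ConditionTaxonomy | None = None,
                     case_id: str | None = None) -> PendingCase:
    """Draw one arriving patient: condition, difficulty band, scope flag."""
    tax = taxonomy or default_taxonomy()
    if rng.random() < config.out_of_19_prob:
        rare = tax.supplementary_rare
        condition = rare[int(rng.integers(len(rare)))]
        return PendingCase(
            case_id=case_id or f"p{day:04d}_{rng.integers(10**6):06d}",
            kind="real", condition=condition, in_19=False, day=day,
        )
    dist = config.condition_distribution or default_condition_distribution(tax)
    rcs = sorted(dist)
    probs = np.asarray([dist[rc] for rc in rcs], dtype=float)
    probs /= probs.sum()
    condition = rcs[int(rng.choice(len(rcs), p=probs))]
    bands = sorted(config.difficulty_distribution)
    bw = np.asarray([config.difficulty_distribution[b] for b in bands])
    band = bands[int(rng.choice(len(bands), p=bw / bw.sum()))]
    return PendingCase(
        case_id=case_id or f"p{day:04d}_{rng.integers(10**6):06d}",
        kind="real", condition=condition, in_19=True, day=day,
        difficulty_band=band, difficulty_score=difficulty_score(band),
    )


def simulate_response(behavior: ResidentBehavior, case: PendingCase,
                      rng: np.random.Generator) -> Tuple[int, int]:
    """One OSCE encounter: returns (performance score, grade).

    Wrong diagnosis scores 0/0; otherwise the checked-box fraction is
    banded into the 1-5 performance score and the case difficulty added.
    The resident's skill updates on feedback.
    """
    rc = case.condition
    correct = rng.random() < behavior.p_correct(rc, case.difficulty_band)
    if not correct:
        performance = grade = 0
    else:
        frac = behavior.checklist_fraction(rc, rng)
        points = int(round(frac * CHECKLIST_BOXES))
        performance = performance_band(100.0 * points / CHECKLIST_BOXES)
        grade = compute_grade(performance, case.difficulty_score)
    behavior.learn(rc, case.day)
    return performance, grade


@dataclass
class SimReport:
    config: dict
    totals: Dict[str, int]
    coverage: Dict[str, Dict[str, int]]  # resident -> RC -> case count
    best_grades: Dict[str, Dict[str, Optional[int]]]
    goal_timeline: List[dict]  # per month: residents meeting each goal
    teaching_files: Dict[str, dict]
    n_decisions: int
    n_real_cases: int

    @property
    def min_total(self) -> int:
        return min(self.totals.values())

    @property
    def max_total(self) -> int:
        return max(self.totals.values())

    @property
    def gini(self) -> float:
        x = np.sort(np.asarray(list(self.totals.values()), dtype=float))
        n = x.size
        if x.sum() == 0:
            return 0.0
        return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum()))

    @property
    def min_rc_count(self) -> int:
        return min(c for row in self.coverage.values() for c in row.values())

    @property
    def min_best_grade(self) -> int:
        """Min over (resident, RC) of the best grade; 0 where none recorded."""
        return min((g if g is not None else 0)
                   for row in self.best_grades.values()
                   for g in row.values())

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "totals": self.totals,
            "coverage": self.coverage,
            "best_grades": self.best_grades,
            "goal_timeline": self.goal_timeline,
            "teaching_files": self.teaching_files,
            "n_decisions": self.n_decisions,
            "n_real_cases": self.n_real_cases,
            "summary": {
                "min_total": self.min_total,
                "max_total": self.max_total,
                "gini": self.gini,
                "min_rc_count": self.min_rc_count,
                "min_best_grade": self.min_best_grade,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())


def run_year(config: SimConfig | None = None,
             taxonomy: ConditionTaxonomy | None = None
             ) -> Tuple[SimReport, List[AllocationDecision]]:
    """Simulate the 10-month allocation period day by day."""
    config = config or SimConfig()
    tax = taxonomy or default_taxonomy()
    rng = np.random.default_rng(config.seed)
    engine_seed = int(np.random.default_rng(config.seed + 1).integers(2 ** 31))
    state = EngineState.new(
        [f"res{i:02d}" for i in range(config.n_residents)],
        config=EngineConfig(daily_cap=config.daily_cap,
                            days_per_month=config.days_per_month,
                            supplementary_months=tuple(
                                config.supplementary_months),
                            seed=engine_seed),
        taxonomy=tax,
    )
    behaviors = {
        r.resident_id: ResidentBehavior(
            resident_id=r.resident_id,
            skill={rc: float(rng.normal(config.skill_mean, config.skill_sd))
                   for rc in tax.allocation_level},
            config=config,
        )
        for r in state.residents
    }

    def respond(resident_id: str, case: PendingCase) -> Tuple[int, int]:
        return simulate_response(behaviors[resident_id], case, rng)

    def virtual_factory(rc: str, day: int) -> PendingCase:
        bands = sorted(config.difficulty_distribution)
        bw = np.asarray([config.difficulty_distribution[b] for b in bands])
        band = bands[int(state.rng.choice(len(bands), p=bw / bw.sum()))]
        return PendingCase(
            case_id=f"v{day:04d}_{state.rng.integers(10**6):06d}",
            kind="virtual", condition=rc, in_19=True, day=day,
            difficulty_band=band, difficulty_score=difficulty_score(band),
        )

    goal_timeline: List[dict] = []
    n_real = 0
    for day in range(config.allocation_days):
        arrivals = int(rng.poisson(config.arrival_mean))
        cases = [generate_patient(day, config, rng, tax) for _ in range(arrivals)]
        n_real += len(cases)
        run_day(cases, state, respond=respond, virtual_factory=virtual_factory)
        if (day + 1) % config.days_per_month == 0:
            statuses = [goal_status(r.file) for r in state.residents]
            goal_timeline.append({
                "month": state.month - 1 if state.day % config.days_per_month == 0
                else state.month,
                "goal1": sum(s[0] for s in statuses),
                "goal2": sum(s[1] for s in statuses),
                "goal3": sum(s[2] for s in statuses),
            })

    report = SimReport(
        config={
            "n_residents": config.n_residents,
            "annual_patients": config.annual_patients,
            "allocation_days": config.allocation_days,
            "out_of_19_prob": config.out_of_19_prob,
            "always_correct": config.always_correct,
            "seed": config.seed,
        },
        totals={r.resident_id: r.cases_total for r in state.residents},
        coverage={
            r.resident_id: {rc: log.n_cases
                            for rc, log in r.file.conditions.items()}
            for r in state.residents
        },
        best_grades={
            r.resident_id: {rc: log.best_grade
                            for rc, log in r.file.conditions.items()}
            for r in state.residents
        },
        goal_timeline=goal_timeline,
        teaching_files={r.resident_id: r.file.to_dict()
                        for r in state.residents},
        n_decisions=len(state.decisions),
        n_real_cases=n_real,
    )
    return report, state.decisions
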