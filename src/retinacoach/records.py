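"""OSCE checklist scoring, grades, and resident teaching files.

After each case the attending expert grades the resident with an OSCE
(Objective Structured Clinical Examination) checklist for the validated
condition: one point per checked box, but zero points overall if the
diagnosis is wrong.  The percentage of boxes earned maps to a performance
score 1–5 in 20-point bands; the final grade adds the case difficulty score
(1/3/5), so grades live in {0} ∪ [2, 10] and the per-condition educational
goal is a grade >= 7.

The teaching file is the allocation engine's entire picture of a resident:
per-RC case counts, grades, and the day of last encounter, plus a seen-flag
per supplementary-rare class and a count of ungraded out-of-scope cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

from .taxonomy import GOAL_GRADE, ConditionTaxonomy, default_taxonomy

__all__ = [
    "OSCEChecklist",
    "OSCEResult",
    "CaseRecord",
    "ConditionLog",
    "TeachingFile",
    "load_checklist_template",
    "score_checklist",
    "performance_band",
    "compute_grade",
    "update_teaching_file",
    "goal_status",
]


@dataclass
class OSCEChecklist:
    """A filled-in OSCE checklist: named sections of 1-point boxes."""

    condition: str
    sections: Dict[str, List[bool]]
    diagnosis_correct: bool

    @property
    def total(self) -> int:
        return sum(len(items) for items in self.sections.values())

    @property
    def points(self) -> int:
        return sum(sum(items) for items in self.sections.values())


@dataclass(frozen=True)
class OSCEResult:
    points: int
    total: int
    percentage: float
    performance_score: int  # 0 iff diagnosis wrong


@dataclass
class CaseRecord:
    """One graded (or deliberately ungraded) resident-case encounter."""

    case_id: str
    condition: str  # expert-validated allocation-level code
    kind: str  # "real" | "virtual"
    day: int
    difficulty_score: Optional[int] = None  # 1|3|5, None for out-of-19 cases
    performance_score: Optional[int] = None
    grade: Optional[int] = None


def load_checklist_template(condition: str = "DR") -> OSCEChecklist:
    """Load a packaged checklist template with all boxes unchecked.

    The diabetic-retinopathy file (37 boxes) ships with the package; it is
    the worked reference template.
    """
    if condition != "DR":
        raise KeyError(f"no packaged checklist template for {condition!r}")
    raw = resources.files("retinacoach.data").joinpath("osce_dr.json").read_text()
    doc = json.loads(raw)
    return OSCEChecklist(
        condition=doc["condition"],
        sections={name: [False] * len(items) for name, items in doc["sections"].items()},
        diagnosis_correct=False,
    )


def performance_band(percentage: float) -> int:
    """Band an exact percentage into the 1–5 performance score.

    Bands have closed upper bounds: (0,20]→1, (20,40]→2, (40,60]→3,
    (60,80]→4, (80,100]→5.  0% still earns score 1 when the diagnosis is
    correct (the printed bands start at 0).
    """
    if not 0.0 <= percentage <= 100.0:
        raise ValueError(f"percentage {percentage} outside [0, 100]")
    for bound, score in ((20, 1), (40, 2), (60, 3), (80, 4)):
        if percentage <= bound:
            return score
    return 5


def score_checklist(checklist: OSCEChecklist) -> OSCEResult:
    """Score a filled checklist: wrong diagnosis fails with 0 points."""
    total = checklist.total
    if total == 0:
        raise ValueError("checklist has no items")
    if not checklist.diagnosis_correct:
        return OSCEResult(points=0, total=total, percentage=0.0, performance_score=0)
    points = checklist.points
    pct = 100.0 * points / total
    return OSCEResult(points=points, total=total, percentage=pct,
                      performance_score=performance_band(pct))


def compute_grade(performance_score: int, difficulty_score: int) -> int:
    """Final grade: performance (1-5) + difficulty (1/3/5); 0 stays 0."""
    if performance_score not in (0, 1, 2, 3, 4, 5):
        raise ValueError(f"invalid performance score {performance_score}")
    if difficulty_score not in (1, 3, 5):
        raise ValueError(f"invalid difficulty score {difficulty_score}")
    if performance_score == 0:
        return 0
    return performance_score + difficulty_score


@dataclass
class ConditionLog:
    """Per-RC slice of a teaching file."""

    n_cases: int = 0
    grades: List[int] = field(default_factory=list)
    last_encounter_day: Optional[int] = None

    @property
    def average_grade(self) -> Optional[float]:
        return sum(self.grades) / len(self.grades) if self.grades else None

    @property
    def best_grade(self) -> Optional[int]:
        return max(self.grades) if self.grades else None


@dataclass
class TeachingFile:
    """Per-resident training record driving personalised allocation."""

    resident_id: str
    conditions: Dict[str, ConditionLog] = field(default_factory=dict)
    rare_seen: Dict[str, bool] = field(default_factory=dict)
    out_of_scope_cases: int = 0

    @classmethod
    def new(cls, resident_id: str,
            taxonomy: ConditionTaxonomy | None = None) -> "TeachingFile":
        tax = taxonomy or default_taxonomy()
        return cls(
            resident_id=resident_id,
            conditions={rc: ConditionLog() for rc in tax.allocation_level},
            rare_seen={c: False for c in tax.supplementary_rare},
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "resident_id": self.resident_id,
            "conditions": {
                rc: {
                    "n_cases": log.n_cases,
                    "grades": log.grades,
                    "last_encounter_day": log.last_encounter_day,
                }
                for rc, log in self.conditions.items()
            },
            "rare_seen": self.rare_seen,
            "out_of_scope_cases": self.out_of_scope_cases,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "TeachingFile":
        return cls(
            resident_id=doc["resident_id"],
            conditions={
                rc: ConditionLog(
                    n_cases=entry["n_cases"],
                    grades=list(entry["grades"]),
                    last_encounter_day=entry["last_encounter_day"],
                )
                for rc, entry in doc["conditions"].items()
            },
            rare_seen=dict(doc["rare_seen"]),
            out_of_scope_cases=doc.get("out_of_scope_cases", 0),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TeachingFile":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def update_teaching_file(file: TeachingFile, record: CaseRecord) -> TeachingFile:
    """Record a case under its expert-validated condition (in place).

    A case the model misclassified is filed under the validated condition
    only — the presumptive label leaves no trace.  Cases outside the 19 RCs
    carry no grade or difficulty; supplementary-rare conditions flip a
    seen-flag instead of accruing grades.
    """
    cond = record.condition
    if cond in file.conditions:
        log = file.conditions[cond]
        log.n_cases += 1
        if record.grade is not None:
            log.grades.append(record.grade)
        log.last_encounter_day = record.day
    elif cond in file.rare_seen:
        file.rare_seen[cond] = True
    else:
        raise KeyError(f"unknown condition {cond!r}")
    return file


def goal_status(file: TeachingFile) -> tuple[bool, bool, bool]:
    """Evaluate the three staged educational goals.

    goal1: at least one case of every RC; goal2: at least three; goal3: a
    best grade >= 7 on every RC.
    """
    logs = file.conditions.values()
    goal1 = all(log.n_cases >= 1 for log in logs)
    goal2 = all(log.n_cases >= 3 for log in logs)
    goal3 = all(log.best_grade is not None and log.best_grade >= GOAL_GRADE
                for log in logs)
    return goal1, goal2, goal3
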