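"""Priority-rule case allocation: matching arriving cases to residents.

Cases arrive one at a time with no lookahead.  For each case the engine
refines the candidate resident set through an ordered rule cascade (the
contract equivalent of salience-ordered production rules), stopping as soon
as one resident remains; residual ties break uniformly at random from the
engine's seeded generator.  Every decision logs the chain of rules that
narrowed the field, so allocations can be audited and replayed.

Real cases inside the 19 retinal conditions (RCs) use the cascade

    r3/r4  fewest prior cases of this RC, while the minimum is below 3
    r5     lowest best grade for this RC, while someone is below grade 7
    r6     oldest last encounter of this RC (spacing effect)
    r7     fewest cases in this RC's educational topic
    r8     fewest cases of this RC
    r9     fewest cases over all 19 RCs

Real cases outside the 19 RCs go to the resident with the fewest cases
today, then fewest overall (r3b/r4b), and are additionally broadcast to
every other resident as ungraded virtual cases.  Virtual-case condition
selection mirrors the cascade per resident (r3v–r7v).  At day end every
resident without a case receives one virtual case (the one-case-per-day
floor, r1/r2), staged supplementary virtual cases kick in when the three
educational goals are unmet after months 5, 7 and 9 (r1s/r4s/r5s), and
residents who met all goals see one "supplementary rare" class per day
until each has been seen once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import CaseRecord, TeachingFile, goal_status
from .taxonomy import GOAL_GRADE, ConditionTaxonomy, default_taxonomy

__all__ = [
    "PendingCase",
    "AllocationDecision",
    "EngineConfig",
    "ResidentState",
    "EngineState",
    "select_resident_real_in19",
    "select_resident_real_out19",
    "select_virtual_condition",
    "run_day",
    "write_decision_log",
]

MIN_CASES_PER_RC = 3  # the r3/r4 "up to 3 cases" target


@dataclass
class PendingCase:
    case_id: str
    kind: str  # "real" | "virtual"
    condition: str  # expert-validated condition code
    in_19: bool
    day: int
    difficulty_band: Optional[str] = None
    difficulty_score: Optional[int] = None  # None for out-of-19 cases
    presumptive_condition: Optional[str] = None


@dataclass
class AllocationDecision:
    case_id: str
    resident_id: str
    rule_chain: List[str]
    tie_broken_randomly: bool
    day: int
    kind: str
    condition: str
    graded: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class EngineConfig:
    """Engine knobs.

    ``daily_cap`` bounds assignments per resident per day (the production
    rules' "maximum value"); default suits ~1000 arrivals over 240 days and
    10 residents.  Supplementary stages fire *after* months 5, 7 and 9 for
    goals 1, 2 and 3.  ``start_month`` is the first allocation month (the
    two initiation months receive no allocations).
    """

    daily_cap: int = 2
    supplementary_months: Tuple[int, int, int] = (5, 7, 9)
    days_per_month: int = 24
    start_month: int = 3
    seed: int = 0


@dataclass
class ResidentState:
    resident_id: str
    file: TeachingFile
    cases_today: int = 0
    cases_total: int = 0


@dataclass
class EngineState:
    residents: List[ResidentState]
    config: EngineConfig = field(default_factory=EngineConfig)
    taxonomy: ConditionTaxonomy = field(default_factory=default_taxonomy)
    day: int = 0  # allocation-day index, 0-based
    decisions: List[AllocationDecision] = field(default_factory=list)
    queued: List[PendingCase] = field(default_factory=list)
    rng: np.random.Generator = None

    def __post_init__(self):
        if self.rng is None:
            self.rng = np.random.default_rng(self.config.seed)

    @classmethod
    def new(cls, resident_ids: Sequence[str],
            config: EngineConfig | None = None,
            taxonomy: ConditionTaxonomy | None = None) -> "EngineState":
        tax = taxonomy or default_taxonomy()
        return cls(
            residents=[ResidentState(r, TeachingFile.new(r, tax))
                       for r in resident_ids],
            config=config or EngineConfig(),
            taxonomy=tax,
        )

    @property
    def month(self) -> int:
        return self.config.start_month + self.day // self.config.days_per_month


# ---------------------------------------------------------------------------
# cascade helpers

def _refine(candidates: List[ResidentState], key: Callable[[ResidentState], float]
            ) -> List[ResidentState]:
    best = min(key(r) for r in candidates)
    return [r for r in candidates if key(r) == best]


def _pick(candidates: List[ResidentState], rng: np.random.Generator
          ) -> Tuple[ResidentState, bool]:
    if len(candidates) == 1:
        return candidates[0], False
    return candidates[int(rng.integers(len(candidates)))], True


def _rc_count(r: ResidentState, rc: str) -> int:
    return r.file.conditions[rc].n_cases


def _rc_best_grade(r: ResidentState, rc: str) -> int:
    best = r.file.conditions[rc].best_grade
    return best if best is not None else -1


def _rc_last_day(r: ResidentState, rc: str) -> int:
    last = r.file.conditions[rc].last_encounter_day
    return last if last is not None else -1


def _topic_count(r: ResidentState, taxonomy: ConditionTaxonomy, topic: str) -> int:
    return sum(r.file.conditions[rc].n_cases
               for rc in taxonomy.topics[topic])


def _total_rc_count(r: ResidentState) -> int:
    return sum(log.n_cases for log in r.file.conditions.values())


def select_resident_real_in19(case: PendingCase,
                              state: EngineState) -> AllocationDecision:
    """Choose the examining resident for a real case within the 19 RCs."""
    rc = case.condition
    chain: List[str] = []
    candidates = [r for r in state.residents
                  if r.cases_today < state.config.daily_cap]
    if not candidates:
        warnings.warn(f"all residents at the daily cap on day {case.day}; "
                      "cap relaxed for this case")
        chain.append("cap_relaxed")
        candidates = list(state.residents)
    chain.append("r2")  # real case, allocated on arrival

    # r3/r4: fewest cases of this RC, only while the minimum is below 3
    min_count = min(_rc_count(r, rc) for r in candidates)
    if min_count < MIN_CASES_PER_RC and len(candidates) > 1:
        candidates = _refine(candidates, lambda r: _rc_count(r, rc))
        chain.append("r3" if min_count == 0 else "r4")
    if len(candidates) > 1:
        # r5: lowest best grade, only while someone is short of the goal
        if min(_rc_best_grade(r, rc) for r in candidates) < GOAL_GRADE:
            candidates = _refine(candidates, lambda r: _rc_best_grade(r, rc))
            chain.append("r5")
    if len(candidates) > 1:
        candidates = _refine(candidates, lambda r: _rc_last_day(r, rc))
        chain.append("r6")
    if len(candidates) > 1:
        topic = state.taxonomy.topic_of(rc)
        candidates = _refine(
            candidates, lambda r: _topic_count(r, state.taxonomy, topic))
        chain.append("r7")
    if len(candidates) > 1:
        candidates = _refine(candidates, lambda r: _rc_count(r, rc))
        chain.append("r8")
    if len(candidates) > 1:
        candidates = _refine(candidates, _total_rc_count)
        chain.append("r9")
    chosen, random_tie = _pick(candidates, state.rng)
    return AllocationDecision(
        case_id=case.case_id, resident_id=chosen.resident_id,
        rule_chain=chain, tie_broken_randomly=random_tie,
        day=case.day, kind=case.kind, condition=rc, graded=True,
    )


def select_resident_real_out19(
    case: PendingCase, state: EngineState
) -> Tuple[AllocationDecision, List[str]]:
    """Examining resident for an out-of-scope real case, plus the broadcast
    list of residents who receive it as an ungraded virtual copy."""
    chain = ["r3b"]
    candidates = _refine(list(state.residents), lambda r: r.cases_today)
    if len(candidates) > 1:
        candidates = _refine(candidates, lambda r: r.cases_total)
        chain.append("r4b")
    chosen, random_tie = _pick(candidates, state.rng)
    broadcast = [r.resident_id for r in state.residents
                 if r.resident_id != chosen.resident_id]
    decision = AllocationDecision(
        case_id=case.case_id, resident_id=chosen.resident_id,
        rule_chain=chain, tie_broken_randomly=random_tie,
        day=case.day, kind=case.kind, condition=case.condition, graded=False,
    )
    return decision, broadcast


def select_virtual_condition(resident: ResidentState, state: EngineState
                             ) -> Tuple[str, List[str]]:
    """Pick which RC a resident's next virtual case should present."""
    tax = state.taxonomy
    rcs = list(tax.allocation_level)
    chain: List[str] = []
    counts = {rc: _rc_count(resident, rc) for rc in rcs}
    min_count = min(counts.values())
    candidates = rcs
    if min_count < MIN_CASES_PER_RC:
        candidates = [rc for rc in rcs if counts[rc] == min_count]
        chain.append("r3v" if min_count == 0 else "r4v")
    if len(candidates) > 1:
        grades = {rc: _rc_best_grade(resident, rc) for rc in candidates}
        if min(grades.values()) < GOAL_GRADE:
            low = min(grades.values())
            candidates = [rc for rc in candidates if grades[rc] == low]
            chain.append("r5v")
    if len(candidates) > 1:
        last = {rc: _rc_last_day(resident, rc) for rc in candidates}
        oldest = min(last.values())
        candidates = [rc for rc in candidates if last[rc] == oldest]
        chain.append("r6v")
    if len(candidates) > 1:
        low = min(counts[rc] for rc in candidates)
        candidates = [rc for rc in candidates if counts[rc] == low]
        chain.append("r7v")
    if len(candidates) > 1:
        chosen = candidates[int(state.rng.integers(len(candidates)))]
    else:
        chosen = candidates[0]
    return chosen, chain


# ---------------------------------------------------------------------------
# day loop

#: respond(resident_id, case) -> (performance_score, grade); the simulator
#: or clinic front-end supplies this.  Graded cases must return both.
RespondFn = Callable[[str, PendingCase], Tuple[int, int]]
#: virtual_case(rc, day) -> PendingCase drawn from the virtual pool
VirtualFactory = Callable[[str, int], PendingCase]


def _default_virtual_factory(state: EngineState) -> VirtualFactory:
    from .taxonomy import difficulty_score

    def factory(rc: str, day: int) -> PendingCase:
        band = ("easy", "medium", "difficult")[int(state.rng.integers(3))]
        return PendingCase(
            case_id=f"v{day:04d}_{state.rng.integers(10**6):06d}",
            kind="virtual", condition=rc, in_19=True, day=day,
            difficulty_band=band, difficulty_score=difficulty_score(band),
        )

    return factory


def _record_assignment(state: EngineState, resident: ResidentState,
                       case: PendingCase, decision: AllocationDecision,
                       respond: Optional[RespondFn]) -> None:
    resident.cases_today += 1
    resident.cases_total += 1
    state.decisions.append(decision)
    file = resident.file
    if case.condition in file.conditions:
        performance = grade = None
        if decision.graded and respond is not None:
            performance, grade = respond(resident.resident_id, case)
        file.conditions[case.condition].n_cases += 1
        if grade is not None:
            file.conditions[case.condition].grades.append(grade)
        file.conditions[case.condition].last_encounter_day = case.day
    elif case.condition in file.rare_seen:
        file.rare_seen[case.condition] = True
    else:
        file.out_of_scope_cases += 1


def _assign_virtual(state: EngineState, resident: ResidentState,
                    rule_prefix: List[str], respond: Optional[RespondFn],
                    virtual_factory: VirtualFactory) -> None:
    rc, chain = select_virtual_condition(resident, state)
    case = virtual_factory(rc, state.day)
    decision = AllocationDecision(
        case_id=case.case_id, resident_id=resident.resident_id,
        rule_chain=rule_prefix + chain, tie_broken_randomly=not chain,
        day=state.day, kind="virtual", condition=rc, graded=True,
    )
    _record_assignment(state, resident, case, decision, respond)


def run_day(real_cases: Sequence[PendingCase], state: EngineState,
            respond: Optional[RespondFn] = None,
            virtual_factory: Optional[VirtualFactory] = None,
            ) -> List[AllocationDecision]:
    """Allocate one day's arriving real cases, then apply the daily floors.

    Order of play: real cases on arrival; day-end virtual fill for every
    resident with no case yet (r1); staged supplementary virtual cases for
    residents missing goal 1/2/3 after months 5/7/9; one supplementary-rare
    virtual case for residents who met all three goals.
    """
    if virtual_factory is None:
        virtual_factory = _default_virtual_factory(state)
    start = len(state.decisions)
    for r in state.residents:
        r.cases_today = 0

    by_id = {r.resident_id: r for r in state.residents}
    for case in real_cases:
        if case.in_19:
            decision = select_resident_real_in19(case, state)
            _record_assignment(state, by_id[decision.resident_id], case,
                               decision, respond)
        else:
            decision, broadcast = select_resident_real_out19(case, state)
            _record_assignment(state, by_id[decision.resident_id], case,
                               decision, respond)
            for rid in broadcast:  # ungraded virtual copies of the rare case
                copy = PendingCase(
                    case_id=f"{case.case_id}_copy_{rid}", kind="virtual",
                    condition=case.condition, in_19=False, day=case.day,
                )
                copy_decision = AllocationDecision(
                    case_id=copy.case_id, resident_id=rid,
                    rule_chain=["r3b_broadcast"], tie_broken_randomly=False,
                    day=case.day, kind="virtual", condition=case.condition,
                    graded=False,
                )
                _record_assignment(state, by_id[rid], copy, copy_decision,
                                   respond)

    # r1: the one-case-per-day floor, filled with virtual cases (r2 shortage)
    for r in state.residents:
        if r.cases_today == 0:
            _assign_virtual(state, r, ["r1", "r2_virtual"], respond,
                            virtual_factory)

    # staged supplementary virtual cases (Table 10) and the rare-class tail
    m1, m2, m3 = state.config.supplementary_months
    for r in state.residents:
        goal1, goal2, goal3 = goal_status(r.file)
        trigger = None
        if state.month > m1 and not goal1:
            trigger = "r1s"
        elif state.month > m2 and not goal2:
            trigger = "r4s"
        elif state.month > m3 and not goal3:
            trigger = "r5s"
        if trigger is not None:
            _assign_virtual(state, r, [trigger], respond, virtual_factory)
        elif goal1 and goal2 and goal3:
            unseen = [c for c, seen in r.file.rare_seen.items() if not seen]
            if unseen:
                rare = unseen[int(state.rng.integers(len(unseen)))]
                case = PendingCase(
                    case_id=f"rare{state.day:04d}_{r.resident_id}",
                    kind="virtual", condition=rare, in_19=False,
                    day=state.day,
                )
                decision = AllocationDecision(
                    case_id=case.case_id, resident_id=r.resident_id,
                    rule_chain=["rare_supplementary"],
                    tie_broken_randomly=len(unseen) > 1,
                    day=state.day, kind="virtual", condition=rare,
                    graded=False,
                )
                _record_assignment(state, r, case, decision, respond)

    state.day += 1
    return state.decisions[start:]


def write_decision_log(decisions: Sequence[AllocationDecision], path) -> None:
    """JSONL decision log, one record per allocation."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in decisions:
            fh.write(json.dumps(d.to_dict()) + "\n")
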