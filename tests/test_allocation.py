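import copy

import numpy as np
import pytest

from retinacoach.allocation import (EngineConfig, EngineState, PendingCase,
                                    run_day, select_resident_real_in19,
                                    select_resident_real_out19,
                                    select_virtual_condition)
from retinacoach.records import CaseRecord, update_teaching_file


def make_state(n_residents=3, seed=0, **config):
    return EngineState.new([chr(ord("A") + i) for i in range(n_residents)],
                           config=EngineConfig(seed=seed, **config))


def give_cases(state, resident, rc, n, grade=8, start_day=0):
    r = next(x for x in state.residents if x.resident_id == resident)
    for i in range(n):
        update_teaching_file(r.file, CaseRecord(
            case_id=f"{resident}{rc}{i}", condition=rc, kind="real",
            day=start_day + i, difficulty_score=3,
            performance_score=min(grade - 3, 5), grade=grade))
        r.cases_total += 1


def real_case(condition="C6", day=0, case_id="p1", band="medium"):
    return PendingCase(case_id=case_id, kind="real", condition=condition,
                       in_19=True, day=day, difficulty_band=band,
                       difficulty_score={"easy": 1, "medium": 3,
                                         "difficult": 5}[band])


class TestRealIn19Cascade:
    def test_fewest_cases_of_condition_wins(self):
        state = make_state()
        give_cases(state, "B", "C6", 2)
        give_cases(state, "C", "C6", 3)
        decision = select_resident_real_in19(real_case("C6"), state)
        assert decision.resident_id == "A"
        assert "r3" in decision.rule_chain

    def test_lowest_best_grade_wins_once_counts_saturate(self):
        state = make_state()
        give_cases(state, "A", "C6", 3, grade=8)
        give_cases(state, "B", "C6", 3, grade=5)
        give_cases(state, "C", "C6", 3, grade=9)
        decision = select_resident_real_in19(real_case("C6"), state)
        assert decision.resident_id == "B"
        assert "r5" in decision.rule_chain

    def test_oldest_encounter_wins_after_grades_met(self):
        state = make_state()
        give_cases(state, "A", "C6", 3, grade=8, start_day=10)
        give_cases(state, "B", "C6", 3, grade=8, start_day=0)
        give_cases(state, "C", "C6", 3, grade=8, start_day=20)
        decision = select_resident_real_in19(real_case("C6", day=30), state)
        assert decision.resident_id == "B"
        assert "r6" in decision.rule_chain

    def test_topic_count_breaks_recency_ties(self):
        state = make_state()
        for rid in "ABC":
            give_cases(state, rid, "C6", 3, grade=8, start_day=0)
        # C13 shares topic T4 with C6; load A and C with topic cases
        give_cases(state, "A", "C13", 2, start_day=5)
        give_cases(state, "C", "C13", 1, start_day=5)
        decision = select_resident_real_in19(real_case("C6", day=30), state)
        assert decision.resident_id == "B"
        assert "r7" in decision.rule_chain

    def test_random_tie_break_is_seeded(self):
        decisions = [select_resident_real_in19(real_case(), make_state(seed=4))
                     for _ in range(3)]
        assert len({d.resident_id for d in decisions}) == 1
        assert all(d.tie_broken_randomly for d in decisions)

    def test_cascade_audit_replay(self):
        """Re-running the selector on a copy of the logged state reproduces
        the decision (the rule chain is sound)."""
        state = make_state(seed=1)
        give_cases(state, "B", "C6", 1)
        snapshot = copy.deepcopy(state)
        decision = select_resident_real_in19(real_case("C6"), state)
        replay = select_resident_real_in19(real_case("C6"), snapshot)
        assert replay.resident_id == decision.resident_id
        assert replay.rule_chain == decision.rule_chain


class TestRealOut19:
    def out19_case(self, day=0):
        return PendingCase(case_id="q1", kind="real", condition="C12",
                           in_19=False, day=day)

    def test_fewest_cases_today_then_overall(self):
        state = make_state()
        by_id = {r.resident_id: r for r in state.residents}
        by_id["A"].cases_today = 2
        by_id["B"].cases_today = 1
        by_id["C"].cases_today = 1
        by_id["B"].cases_total = 30
        by_id["C"].cases_total = 20
        decision, broadcast = select_resident_real_out19(self.out19_case(),
                                                         state)
        assert decision.resident_id == "C"
        assert sorted(broadcast) == ["A", "B"]
        assert decision.graded is False
        assert decision.rule_chain == ["r3b", "r4b"]

    def test_single_resident_gets_empty_broadcast(self):
        state = make_state(n_residents=1)
        decision, broadcast = select_resident_real_out19(self.out19_case(),
                                                         state)
        assert decision.resident_id == "A" and broadcast == []


class TestVirtualConditionCascade:
    def test_unseen_condition_first(self):
        state = make_state(n_residents=1)
        r = state.residents[0]
        for rc in r.file.conditions:
            if rc != "C7":
                give_cases(state, "A", rc, 1)
        rc, chain = select_virtual_condition(r, state)
        assert rc == "C7" and chain[0] == "r3v"

    def test_lowest_grade_condition_once_counts_saturate(self):
        state = make_state(n_residents=1)
        r = state.residents[0]
        for rc in r.file.conditions:
            give_cases(state, "A", rc, 3, grade=5 if rc == "C9" else 8)
        rc, chain = select_virtual_condition(r, state)
        assert rc == "C9" and "r5v" in chain

    def test_oldest_encounter_once_goals_met(self):
        state = make_state(n_residents=1)
        r = state.residents[0]
        for i, rc in enumerate(r.file.conditions):
            give_cases(state, "A", rc, 3, grade=8,
                       start_day=0 if rc == "C14" else 10 + i)
        rc, chain = select_virtual_condition(r, state)
        assert rc == "C14" and "r6v" in chain


class TestRunDay:
    def respond(self, resident_id, case):
        return 4, 7

    def test_real_cases_plus_daily_floor(self):
        state = make_state()
        cases = [real_case("C6", case_id="p1"), real_case("DR", case_id="p2")]
        decisions = run_day(cases, state, respond=self.respond)
        assert len(decisions) == 3  # 2 real + 1 virtual fill
        assert sum(d.kind == "real" for d in decisions) == 2
        assert min(r.cases_today for r in state.residents) >= 1

    def test_no_real_cases_everyone_gets_a_virtual(self):
        state = make_state()
        decisions = run_day([], state, respond=self.respond)
        assert len(decisions) == 3
        assert all(d.kind == "virtual" for d in decisions)

    def test_out19_broadcast_reaches_everyone_ungraded(self):
        state = make_state()
        case = PendingCase(case_id="q", kind="real", condition="C12",
                           in_19=False, day=0)
        decisions = run_day([case], state, respond=self.respond)
        ungraded = [d for d in decisions if not d.graded]
        assert len(ungraded) == 3  # examiner + 2 virtual copies
        assert all(r.file.rare_seen["C12"] for r in state.residents)

    def test_supplementary_case_after_month_five(self):
        # month > 5 with goal1 unmet triggers one extra virtual case
        state = make_state(days_per_month=1, start_month=6)
        state.day = 1  # month 7
        decisions = run_day([real_case("C6")], state, respond=self.respond)
        per_resident = {r.resident_id: r.cases_today
                        for r in state.residents}
        assert all(n >= 2 for rid, n in per_resident.items())
        assert any("r1s" in d.rule_chain for d in decisions)

    def test_conservation_every_real_case_examined_once(self):
        state = make_state()
        cases = [real_case("C6", case_id=f"p{i}") for i in range(5)]
        decisions = run_day(cases, state, respond=self.respond)
        real = [d for d in decisions if d.kind == "real"]
        assert sorted(d.case_id for d in real) == sorted(c.case_id
                                                         for c in cases)

    def test_determinism(self):
        def play(seed):
            state = make_state(seed=seed)
            out = []
            for day in range(5):
                cases = [real_case("C6", day=day, case_id=f"p{day}")]
                out += run_day(cases, state, respond=self.respond)
            return [(d.case_id, d.resident_id, tuple(d.rule_chain))
                    for d in out]

        assert play(3) == play(3)
        assert play(3) != play(4) or True  # different seeds may still agree
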