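"""Simulation engine: queueing, routing, shifts, conservation."""

import math

import numpy as np
import pytest

from wardflow.engine import (
    TICKS_PER_MINUTE,
    SimClock,
    Simulation,
    current_wait,
    run_scenario,
)
from wardflow.scenario import (
    EXIT,
    AttendanceType,
    FlowEdge,
    Room,
    ScenarioConfig,
    ShiftRoster,
    Stage,
    StaffMember,
)
from wardflow.workload import WorkloadProfile


def single_room_scenario(lower=10, mode=10, upper=10, posts=1):
    """One care room fed directly by the entry stage."""
    rooms = {
        "care": Room(
            "care", required_specialty="carer", station_limit=4,
            attendance_types=(AttendanceType("visit", lower, mode, upper),),
        )
    }
    stages = {"care": Stage("care", "care", ("visit",))}
    flow = {"care": [FlowEdge("care", EXIT, 1.0)]}
    post_map = {f"p{i}": "care" for i in range(posts)}
    staff = [
        StaffMember(f"p{i}-{letter}", frozenset({"carer"}), ShiftRoster(f"p{i}", off))
        for i in range(posts)
        for letter, off in zip("abcd", (0, 12, 24, 36))
    ]
    return ScenarioConfig(
        rooms=rooms, staff=staff, stages=stages, flow=flow, posts=post_map,
        entry_stage="care",
    )


class TestCurrentWait:
    class Stub:
        def __init__(self, queue, active):
            self.queue_len, self.active = queue, active

    def test_worked_example(self):
        assert current_wait(self.Stub(4, 1), 10) == 40

    def test_empty_queue(self):
        assert current_wait(self.Stub(0, 2), 10) == 0

    def test_doubling_attendants_halves(self):
        assert current_wait(self.Stub(6, 2), 10) == current_wait(self.Stub(6, 1), 10) / 2

    def test_unstaffed_room_is_infinite(self):
        assert current_wait(self.Stub(3, 0), 10) == math.inf

    def test_requires_positive_act(self):
        with pytest.raises(ValueError):
            current_wait(self.Stub(3, 1), 0)


class TestSimClock:
    def test_unit_conversions(self):
        assert SimClock.minutes_to_ticks(10) == 60
        assert SimClock.ticks_to_minutes(360) == 60
        clock = SimClock()
        clock.advance()
        assert clock.tick == 1 and clock.minutes == pytest.approx(1 / 6)


class TestStepSemantics:
    def test_empty_hospital_is_a_fixed_point(self):
        sc = single_room_scenario()
        sim = Simulation(sc, WorkloadProfile("constant", 0.0), seed=0,
                         duration_minutes=60.0)
        log = sim.run()
        assert log.entered == 0 and log.exited == 0
        assert all(r.queue_len == 0 for r in sim.rooms.values())

    def test_second_simultaneous_arrival_waits_one_service(self):
        # one attendant, two arrivals at t0, deterministic 10-minute care:
        # the first waits 0, the second waits exactly 10 minutes
        sc = single_room_scenario(10, 10, 10, posts=1)
        sim = Simulation(sc, WorkloadProfile("constant", 0.0), seed=0,
                         duration_minutes=60.0)
        sim._admit(0)
        sim._admit(0)
        for now in range(sim.duration_ticks):
            sim.step(now)
        log = sim.log
        log.visits = sorted(log.visits)
        waits = [(start - enq) / TICKS_PER_MINUTE
                 for (_p, _s, _r, enq, start, _e) in log.visits]
        assert waits == [0.0, 10.0]

    def test_patient_routed_to_valid_successor_stages(self, clinic):
        log = run_scenario(
            clinic, WorkloadProfile("constant", 0.02), seed=3,
            duration_minutes=1440.0,
        )
        frame = log.visits_frame()
        by_patient = frame.groupby("patient")["stage"].apply(list)
        successors = {
            "reception": {"triage"},
            "triage": {"doctor_first"},
            "doctor_first": {
                "xray", "lab", "ecg",
                "med_intravenous", "med_intramuscular", "med_inhalation",
            },
            "xray": {"doctor_return"},
            "lab": {"doctor_return"},
            "ecg": {"doctor_return"},
            "doctor_return": {
                "xray", "lab", "ecg",
                "med_intravenous", "med_intramuscular", "med_inhalation",
            },
        }
        checked = 0
        for stages in by_patient:
            for a, b in zip(stages, stages[1:]):
                assert b in successors[a], (a, b)
                checked += 1
        assert checked > 50

    def test_care_durations_within_recipe_support(self, clinic):
        log = run_scenario(
            clinic, WorkloadProfile("constant", 0.02), seed=4,
            duration_minutes=720.0,
        )
        frame = log.visits_frame()
        frame["minutes"] = (frame["end"] - frame["start"]) / TICKS_PER_MINUTE
        triage = frame[frame["stage"] == "triage"]["minutes"]
        assert triage.between(5 - 0.1, 10 + 0.1).all()
        iv = frame[frame["stage"] == "med_intravenous"]["minutes"]
        if len(iv):
            assert iv.between(40.5 - 0.1, 122.5 + 0.1).all()


class TestRunScenario:
    def test_static_staffing_is_time_invariant(self, clinic):
        log = run_scenario(
            clinic, WorkloadProfile("wave", 0.02), seed=1,
            duration_minutes=2 * 1440.0,
        )
        assert log.hourly_active_min.min() == 11
        assert log.hourly_active_max.max() == 11

    def test_same_seed_gives_identical_logs(self, clinic):
        kw = dict(controller_mode="reactive", seed=7, duration_minutes=1440.0)
        a = run_scenario(clinic, WorkloadProfile("wave", 0.03), **kw)
        b = run_scenario(clinic, WorkloadProfile("wave", 0.03), **kw)
        assert a.visits == b.visits
        assert np.array_equal(a.hourly_max_wait, b.hourly_max_wait)
        assert a.movements == b.movements

    @pytest.mark.parametrize("mode", ["none", "reactive"])
    def test_patient_conservation(self, clinic, mode):
        log = run_scenario(
            clinic, WorkloadProfile("ascending", 0.04), controller_mode=mode,
            seed=5, duration_minutes=1440.0,
        )
        assert log.entered > 0
        assert log.conserved()

    def test_duration_must_align_with_cycles(self, clinic):
        with pytest.raises(ValueError):
            run_scenario(clinic, WorkloadProfile("constant", 0.01),
                         duration_minutes=15.0)

    def test_unknown_mode_rejected(self, clinic):
        with pytest.raises(ValueError):
            run_scenario(clinic, WorkloadProfile("constant", 0.01),
                         controller_mode="psychic", duration_minutes=60.0)


class TestServiceInvariants:
    def test_no_attendant_serves_two_patients_and_limits_hold(self, clinic):
        sim = Simulation(
            clinic, WorkloadProfile("constant", 0.05), seed=2,
            duration_minutes=360.0,
        )
        for now in range(sim.duration_ticks):
            sim.step(now)
            for room in sim.rooms.values():
                servers = list(room.server_of.values())
                assert len(servers) == len(set(servers))
                assert len(room.busy) <= min(
                    room.active, room.config.station_limit
                )
                for staff_id in room.busy:
                    assert staff_id in room.present

    def test_active_attendants_hold_room_specialty(self, clinic):
        sim = Simulation(
            clinic, WorkloadProfile("wave", 0.04), seed=2,
            duration_minutes=720.0,
        )
        from wardflow.controller_reactive import ReactiveController

        sim.controller = ReactiveController()
        for now in range(sim.duration_ticks):
            sim.step(now)
            if now % 60 == 0:
                for room in sim.rooms.values():
                    for staff_id in room.present:
                        member = sim.staffing.states[staff_id].member
                        assert room.config.required_specialty in member.specialties
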