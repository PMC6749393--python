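"""Threshold-triggered controller: room deltas and hospital orchestration."""

import pytest

from wardflow.controller_reactive import (
    ReactiveController,
    RoomDelta,
    room_delta_reactive,
)
from wardflow.engine import Simulation, run_scenario
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
from wardflow.staffing import ALLOCATE, REALLOCATE
from wardflow.workload import WorkloadProfile


class StubRoom:
    def __init__(self, queue, active, inbound=0, limit=4, name="room"):
        self.name = name
        self.queue_len = queue
        self.active = active
        self.inbound = inbound
        self.config = type("Cfg", (), {"station_limit": limit})()


class TestRoomDelta:
    def test_overloaded_room_requests_one_attendant(self):
        # 4 waiting, ACT 10, one attendant: wait 40 > upper 30; a second
        # attendant brings the estimate to 20 <= 30
        delta = room_delta_reactive(StubRoom(4, 1), 10, upper=30, lower=9)
        assert delta == RoomDelta("room", 1)

    def test_within_band_no_action(self):
        delta = room_delta_reactive(StubRoom(2, 1), 10, upper=30, lower=9)
        assert delta.q == 0

    def test_never_below_one_attendant(self):
        delta = room_delta_reactive(StubRoom(0, 1), 10, upper=30, lower=9)
        assert delta.q == 0

    def test_quiet_room_spares_down_to_one(self):
        delta = room_delta_reactive(StubRoom(0, 3), 10, upper=30, lower=9)
        assert delta.q == -2

    def test_need_capped_at_station_limit(self):
        delta = room_delta_reactive(StubRoom(40, 1, limit=4), 10, upper=30, lower=9)
        assert delta.q == 3  # 1 + 3 == limit even though wait stays high

    def test_inbound_attendants_count_as_supply(self):
        assert room_delta_reactive(StubRoom(4, 1, inbound=1), 10, 30, 9).q == 0

    def test_matches_brute_force_band_search(self, rng):
        # independent oracle: exhaustively choose the attendant count the
        # room-level rule should reach
        for _ in range(300):
            queue = int(rng.integers(0, 30))
            a = int(rng.integers(1, 6))
            limit = int(rng.integers(a, 9))
            act = float(rng.uniform(1, 30))
            upper, lower = 21.0, 9.0
            q = room_delta_reactive(StubRoom(queue, a, limit=limit), act,
                                    upper, lower).q

            def wait(n):
                return queue * act / n if n else float("inf")

            if wait(a) > upper:
                best = next(
                    (n for n in range(1, limit - a + 1) if wait(a + n) <= upper),
                    max(limit - a, 0),
                )
                assert q == best
            elif wait(a) < lower:
                best = 0
                while a - (best + 1) >= 1 and wait(a - (best + 1)) < lower:
                    best += 1
                assert q == -best
            else:
                assert q == 0


def two_room_scenario():
    """Two rooms sharing one specialty, each with its own 4-staff posts."""
    at = AttendanceType("visit", 8, 10, 12)
    rooms = {
        name: Room(name, required_specialty="nurse", station_limit=4,
                   attendance_types=(at,))
        for name in ("alpha", "beta")
    }
    stages = {
        "alpha": Stage("alpha", "alpha", ("visit",)),
        "beta": Stage("beta", "beta", ("visit",)),
    }
    flow = {
        "alpha": [FlowEdge("alpha", EXIT, 1.0)],
        "beta": [FlowEdge("beta", EXIT, 1.0)],
    }
    posts = {"pa1": "alpha", "pa2": "alpha", "pb1": "beta", "pb2": "beta"}
    staff = [
        StaffMember(f"{post}-{letter}", frozenset({"nurse"}),
                    ShiftRoster(post, off))
        for post in posts
        for letter, off in zip("abcd", (0, 12, 24, 36))
    ]
    return ScenarioConfig(rooms=rooms, staff=staff, stages=stages, flow=flow,
                          posts=posts, entry_stage="alpha")


def make_sim(scenario, seed=0):
    return Simulation(scenario, WorkloadProfile("constant", 0.0), seed=seed,
                      duration_minutes=1440.0)


class TestControlCycle:
    def test_surplus_to_needy_single_reallocation(self):
        sim = make_sim(two_room_scenario())
        # alpha overloaded (queue 12 with 2 attendants), beta idle
        for _ in range(12):
            sim._admit(0)
        controller = ReactiveController(upper=21, lower=9)
        orders = controller.orders(sim, cycle=1, now=0)
        reallocs = [o for o in orders if o.kind == REALLOCATE]
        assert reallocs and all(o.to_room == "alpha" for o in reallocs)
        assert all(o.from_room == "beta" for o in reallocs)
        # beta keeps at least one attendant
        assert len(reallocs) <= 1

    def test_all_rooms_in_band_no_orders(self):
        sim = make_sim(two_room_scenario())
        controller = ReactiveController(upper=21, lower=9)
        controller._prev_quiet = False  # not yet quiet long enough
        assert controller.orders(sim, cycle=1, now=0) == []

    def test_unique_specialty_room_gets_allocation_only(self, clinic):
        sim = Simulation(clinic, WorkloadProfile("constant", 0.0), seed=0,
                         duration_minutes=1440.0)
        doctor_stage = "doctor_first"
        for _ in range(14):
            sim.rooms["doctor"].queue.append((sim._next_patient, 0, doctor_stage))
            sim._next_patient += 1
        t = 13 * 360  # an hour when the rested offset-36 doctors may be called
        orders = ReactiveController(21, 9).orders(sim, cycle=78, now=t)
        to_doctor = [o for o in orders if o.to_room == "doctor"]
        assert to_doctor
        assert all(o.kind == ALLOCATE for o in to_doctor)

    def test_reallocation_attempted_before_allocation(self):
        sim = make_sim(two_room_scenario())
        for _ in range(40):
            sim._admit(0)
        orders = ReactiveController(21, 9).orders(sim, cycle=144, now=24 * 360)
        kinds = [o.kind for o in orders if o.kind != "deallocate"]
        if ALLOCATE in kinds and REALLOCATE in kinds:
            assert kinds.index(REALLOCATE) < kinds.index(ALLOCATE)

    @pytest.mark.parametrize("upper,lower", [(27, 15), (21, 15), (27, 9), (21, 9)])
    def test_threshold_combos_run_to_completion(self, clinic, upper, lower):
        log = run_scenario(
            clinic, WorkloadProfile("wave", 0.035), controller_mode="reactive",
            seed=11, duration_minutes=720.0, upper=upper, lower=lower,
        )
        assert log.conserved()
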