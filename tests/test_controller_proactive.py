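"""Predictive controller: room deltas, list scheduling, anticipation."""

import itertools

import numpy as np
import pytest

from wardflow.controller_proactive import (
    ProactiveController,
    list_schedule_reallocation,
    room_delta_predictive,
)
from wardflow.controller_reactive import ReactiveController
from wardflow.engine import Simulation, run_scenario
from wardflow.staffing import ALLOCATE, REALLOCATE
from wardflow.workload import WorkloadProfile

from test_controller_reactive import two_room_scenario


def delta_loop_oracle(a, ect_prime, upper, lower, limit):
    """Independent re-enactment of the room-level predictive while-loops."""

    def wait(a_prime):
        return float("inf") if a_prime == 0 else ect_prime / a_prime

    n, a_prime = 0, a
    if wait(a) > upper:
        while a_prime < limit and wait(a_prime) > upper:
            n += 1
            a_prime = a + n
    elif wait(a) < lower:
        while a_prime > 0 and wait(a_prime) < lower:
            n -= 1
            a_prime = a + n
    return n


class TestRoomDeltaPredictive:
    def test_worked_example(self):
        # predicted 40-minute queue, one attendant, 30-minute upper bound:
        # one extra attendant suffices
        assert room_delta_predictive(1, 40, upper=30, lower=9, limit=4) == 1

    def test_within_band(self):
        assert room_delta_predictive(2, 40, upper=30, lower=9, limit=4) == 0

    def test_exhaustive_equivalence_up_to_limit_8(self):
        # every attendant count, limit and a grid of predicted loads and bands
        ect_values = [0.0, 4.0, 9.0, 18.0, 27.0, 40.0, 80.0, 200.0]
        bands = [(30.0, 9.0), (21.0, 9.0), (27.0, 15.0)]
        checked = 0
        for limit in range(1, 9):
            for a in range(1, limit + 1):
                for ect_prime, (upper, lower) in itertools.product(
                    ect_values, bands
                ):
                    assert room_delta_predictive(
                        a, ect_prime, upper, lower, limit
                    ) == delta_loop_oracle(a, ect_prime, upper, lower, limit)
                    checked += 1
        assert checked == 864

    def test_randomized_equivalence(self, rng):
        for _ in range(1000):
            limit = int(rng.integers(1, 9))
            a = int(rng.integers(1, limit + 1))
            ect_prime = float(rng.uniform(0, 300))
            lower = float(rng.uniform(1, 15))
            upper = lower + float(rng.uniform(1, 30))
            assert room_delta_predictive(a, ect_prime, upper, lower, limit) == \
                delta_loop_oracle(a, ect_prime, upper, lower, limit)


class TestListScheduling:
    def test_reference_walkthrough(self):
        # a room needing 3 with donors {Room2: 3, Room3: 2, Room4: 2} gives
        # two attendants from Room 2, then one from Room 4
        free = [
            ("room2", ["n1", "n2", "n3"]),
            ("room3", ["n4", "n5"]),
            ("room4", ["n6", "n7"]),
        ]
        moves = list_schedule_reallocation("room1", free, demand=3)
        assert [donor for donor, _ in moves] == ["room2", "room2", "room4"]

    def test_zero_demand(self):
        assert list_schedule_reallocation("r", [("a", ["x"])], 0) == []

    def test_partial_fulfilment_and_counting(self, rng):
        for _ in range(200):
            n_rooms = int(rng.integers(1, 6))
            free = [
                (f"r{i}", [f"s{i}_{j}" for j in range(rng.integers(0, 5))])
                for i in range(n_rooms)
            ]
            free.sort(key=lambda item: -len(item[1]))
            demand = int(rng.integers(0, 12))
            moves = list_schedule_reallocation("needy", free, demand)
            total_free = sum(len(staff) for _, staff in free)
            assert len(moves) == min(demand, total_free)
            assert len({s for _, s in moves}) == len(moves)  # no double moves


class TestControlCyclePredictive:
    def test_all_rooms_in_band_no_orders(self):
        sim = Simulation(
            two_room_scenario(), WorkloadProfile("constant", 0.0), seed=0,
            duration_minutes=1440.0,
        )
        controller = ProactiveController(upper=30, lower=9)
        controller._prev_quiet = False
        assert controller.orders(sim, cycle=1, now=0) == []

    def test_forecast_spike_routes_staff_toward_room(self):
        # a scripted arrivals spike in room alpha's series: the controller
        # must order movements into alpha ahead of the spike
        sim = Simulation(
            two_room_scenario(), WorkloadProfile("constant", 0.0), seed=0,
            duration_minutes=1440.0,
        )
        for cycle in range(48):
            ramp = max(0, cycle - 36)
            sim.store["alpha"].append_cycle(
                act_value=10.0, nip_value=float(3 * ramp),
                nwp_value=float(4 * ramp), na_value=2.0, wait_value=0.0,
            )
            sim.store["beta"].append_cycle(0.0, 0.0, 0.0, 2.0, 0.0)
        orders = ProactiveController(upper=30, lower=9).orders(
            sim, cycle=48, now=48 * 60 - 1
        )
        assert orders
        assert all(o.to_room == "alpha" for o in orders if o.kind == REALLOCATE)

    def test_unique_specialty_needs_allocation_only(self, clinic):
        sim = Simulation(
            clinic, WorkloadProfile("constant", 0.0), seed=0,
            duration_minutes=1440.0,
        )
        for _ in range(14):
            sim.rooms["doctor"].queue.append((sim._next_patient, 0, "doctor_first"))
            sim._next_patient += 1
        orders = ProactiveController(30, 9).orders(sim, cycle=78, now=13 * 360)
        to_doctor = [o for o in orders if o.to_room == "doctor"]
        assert to_doctor and all(o.kind == ALLOCATE for o in to_doctor)


class TestHysteresisCooldown:
    def test_no_ping_pong_under_square_wave_demand(self):
        """Alternating two-room demand must not bounce one nurse back and
        forth on consecutive cycles: the cooldown forbids an immediate
        return to the origin room."""
        sim = Simulation(
            two_room_scenario(), WorkloadProfile("constant", 0.0), seed=0,
            duration_minutes=1440.0,
        )
        controller = ReactiveController(upper=21, lower=9)
        now = 0
        moved = []
        for cycle in range(1, 13):
            # square wave: odd cycles load alpha, even cycles load beta
            hot = "alpha" if cycle % 2 else "beta"
            for room in sim.rooms.values():
                room.queue.clear()
            for _ in range(10):
                pid = sim._next_patient
                sim._next_patient += 1
                from wardflow.engine import PatientRecord

                sim.patients[pid] = PatientRecord(pid)
                sim.rooms[hot].queue.append((pid, now, hot))
            orders = controller.orders(sim, cycle, now)
            sim._enact_orders(orders, now)
            for order in orders:
                if order.kind == REALLOCATE:
                    moved.append((cycle, order.staff_id, order.from_room,
                                  order.to_room))
            for _ in range(sim.cycle_ticks):
                sim.step(now)
                now += 1
        # no staff member reverses their previous move on the next cycle
        for (c1, s1, f1, t1), (c2, s2, f2, t2) in zip(moved, moved[1:]):
            if s1 == s2 and c2 == c1 + 1:
                assert not (f2 == t1 and t2 == f1), (
                    f"{s1} ping-ponged {f1}->{t1} then {f2}->{t2}"
                )


class TestAnticipation:
    def test_proactive_orders_before_reactive_on_ramp(self, clinic):
        """On an identical ascending-demand trace, the forecast-driven
        controller issues its first movement order earlier than the
        threshold-driven one."""
        profile = WorkloadProfile("ascending", 0.05)

        def first_order_tick(mode):
            log = run_scenario(
                clinic, profile, controller_mode=mode, seed=9,
                duration_minutes=720.0, collect_visits=False,
            )
            enacted = [
                m["tick"] for m in log.movements
                if m["outcome"].startswith("enacted")
            ]
            return min(enacted) if enacted else None

        proactive = first_order_tick("proactive")
        reactive = first_order_tick("reactive")
        assert proactive is not None and reactive is not None
        assert proactive < reactive
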