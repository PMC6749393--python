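"""Discrete-event simulation engine.

The clock advances in 10-second ticks.  Each tick, in order: (1) services
whose end time has arrived complete and their patients are routed onward
through the flow graph; (2) professionals in transit whose arrival time has
come land in their destination room; (3) roster shift changes and forced
deallocations take effect; (4) new patients admitted by the workload enter at
the hospital entry stage; (5) idle professionals start serving waiting
patients in FIFO order, sampling the care duration from the stage's
triangular recipe at service start; (6) on monitoring-cycle boundaries the
per-room series (average care time, incoming patients, queue lengths,
staffing) are rolled up and the elasticity controller, if any, inspects the
hospital and issues movement orders, which are validated against specialty,
capacity and labor rules before being enacted.

A professional never starts a service that would end after the instant they
must leave (rostered shift end, or the overtime deallocation deadline), which
is how the 12-hour and rest rules hold exactly; the patient at the head of
the queue instead waits for the relieving shift.
"""

from __future__ import annotations

import hashlib
import heapq
import json
import math
from bisect import bisect_right
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import staffing as staffing_mod
from .equations import TimeSeriesStore
from .scenario import EXIT, ScenarioConfig, Stage
from .staffing import ALLOCATE, DEALLOCATE, REALLOCATE, MovementOrder, StaffingState
from .workload import ArrivalAccumulator, WorkloadProfile, integer_arrivals, rate_at

TICK_SECONDS = 10
TICKS_PER_MINUTE = 6
TICKS_PER_HOUR = 360


class SimClock:
    """Discrete 10-second clock with unit helpers."""

    def __init__(self) -> None:
        self.tick = 0

    def advance(self) -> None:
        self.tick += 1

    @property
    def minutes(self) -> float:
        return self.tick / TICKS_PER_MINUTE

    @staticmethod
    def minutes_to_ticks(minutes: float) -> int:
        return int(round(minutes * TICKS_PER_MINUTE))

    @staticmethod
    def ticks_to_minutes(ticks: int) -> float:
        return ticks / TICKS_PER_MINUTE


@dataclass
class PatientRecord:
    id: int
    visits: list[tuple[str, str, int, int, int]] = field(default_factory=list)
    # (stage, room, enqueue, start, end) per visited room
    exit_tick: Optional[int] = None


class RoomState:
    """Dynamic state of one room."""

    __slots__ = (
        "name", "config", "queue", "present", "busy", "server_of", "inbound",
        "cycle_durations", "cycle_arrivals", "na_sum", "recent_durations",
    )

    def __init__(self, config) -> None:
        self.name = config.name
        self.config = config
        self.queue: deque[tuple[int, int, str]] = deque()  # (patient, enqueue, stage)
        self.present: list[str] = []  # active attendants, insertion-ordered
        self.busy: dict[str, tuple[int, int]] = {}  # staff -> (patient, end tick)
        self.server_of: dict[int, str] = {}  # patient -> staff serving them
        self.inbound = 0  # attendants in transit toward this room
        self.cycle_durations: list[float] = []
        self.cycle_arrivals = 0
        self.na_sum = 0
        self.recent_durations: deque[float] = deque(maxlen=500)

    @property
    def active(self) -> int:
        return len(self.present)

    @property
    def queue_len(self) -> int:
        return len(self.queue)


def current_wait(room_state: RoomState, act_estimate: float) -> float:
    """Estimated wait of a newly arriving patient, from measured state.

    Queue length times the average care time, divided by the attendants
    serving in parallel; infinite when the room is unstaffed.
    """
    if act_estimate <= 0:
        raise ValueError("act_estimate must be > 0")
    a = room_state.active
    if a == 0:
        return math.inf
    return room_state.queue_len * act_estimate / a


@dataclass
class SimulationLog:
    """Tick-resolved record of one simulated run."""

    seed: int
    controller_mode: str
    config_hash: str
    duration_ticks: int
    cycle_ticks: int
    n_hours: int
    room_names: list[str]
    # per-hour aggregates
    hourly_max_wait: np.ndarray = None
    hourly_wait_count: np.ndarray = None
    hourly_active_sum: np.ndarray = None
    hourly_active_min: np.ndarray = None
    hourly_active_max: np.ndarray = None
    hourly_onshift_sum: np.ndarray = None
    hourly_overtime_sum: np.ndarray = None
    # per-cycle series and event logs
    store: TimeSeriesStore = None
    visits: list[tuple[int, str, str, int, int, int]] = field(default_factory=list)
    movements: list[dict] = field(default_factory=list)
    rejected_orders: int = 0
    entered: int = 0
    exited: int = 0
    in_system_at_end: int = 0

    def waits_minutes(self) -> np.ndarray:
        """Realized waits (service start minus enqueue) in minutes."""
        return np.array(
            [(v[4] - v[3]) / TICKS_PER_MINUTE for v in self.visits], dtype=float
        )

    def visits_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.visits,
            columns=["patient", "stage", "room", "enqueue", "start", "end"],
        )

    def to_frame(self):
        """Tidy per-cycle, per-room series (queue, wait estimate, staffing)."""
        return self.store.to_frame()

    def movements_frame(self):
        import pandas as pd

        return pd.DataFrame.from_records(
            self.movements,
            columns=["tick", "staff", "kind", "from", "to", "eta", "outcome"],
        )

    def conserved(self) -> bool:
        return self.entered == self.exited + self.in_system_at_end


class Simulation:
    """One simulated hospital run.  Use :func:`run_scenario` for the common
    entry point; instantiate directly for fine-grained control."""

    def __init__(
        self,
        scenario: ScenarioConfig,
        workload: WorkloadProfile,
        controller=None,
        seed: int = 0,
        duration_minutes: float = 7 * 1440.0,
        collect_visits: bool = True,
    ):
        self.scenario = scenario
        self.workload = workload
        self.controller = controller
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.duration_ticks = SimClock.minutes_to_ticks(duration_minutes)
        self.cycle_ticks = SimClock.minutes_to_ticks(scenario.cycle_minutes)
        if self.duration_ticks % self.cycle_ticks:
            raise ValueError("duration must be a whole number of monitoring cycles")
        self.clock = SimClock()
        self.collect_visits = collect_visits

        self.staffing = StaffingState(scenario, TICKS_PER_MINUTE)
        self.rooms: dict[str, RoomState] = {
            name: RoomState(cfg) for name, cfg in scenario.rooms.items()
        }
        self.store = TimeSeriesStore(list(scenario.rooms))
        self.patients: dict[int, PatientRecord] = {}
        self._next_patient = 0
        self.entered = 0
        self.exited = 0
        self.accumulator = ArrivalAccumulator()
        self._fallback_act = {
            name: scenario.expected_service_minutes(name) for name in scenario.rooms
        }

        # fast routing tables
        self._stage: dict[str, Stage] = scenario.stages
        self._route_table: dict[str, tuple[list[str], list[float]]] = {}
        for origin, edges in scenario.flow.items():
            targets = [e.to_stage for e in edges]
            cum = np.cumsum([e.probability for e in edges])
            cum[-1] = 1.0
            self._route_table[origin] = (targets, cum.tolist())

        # event queues
        self._service_heap: list[tuple[int, int, str, int]] = []
        self._transit_heap: list[tuple[int, int, str]] = []
        self._forced_heap: list[tuple[int, str]] = []
        self._seq = 0
        self._shift_events = self._build_shift_events()
        self._shift_ptr = 0

        n_hours = self.duration_ticks // TICKS_PER_HOUR
        self.log = SimulationLog(
            seed=seed,
            controller_mode=getattr(controller, "name", "none"),
            config_hash=self._hash_config(),
            duration_ticks=self.duration_ticks,
            cycle_ticks=self.cycle_ticks,
            n_hours=n_hours,
            room_names=list(scenario.rooms),
            hourly_max_wait=np.zeros(n_hours),
            hourly_wait_count=np.zeros(n_hours, dtype=int),
            hourly_active_sum=np.zeros(n_hours),
            hourly_active_min=np.full(n_hours, np.inf),
            hourly_active_max=np.zeros(n_hours),
            hourly_onshift_sum=np.zeros(n_hours),
            hourly_overtime_sum=np.zeros(n_hours),
            store=self.store,
        )

        # staff on duty at tick 0 take their posts
        for member in scenario.staff:
            if self.staffing.on_duty(member.id, 0):
                room = self.staffing.begin_shift(member.id, 0)
                self.rooms[room].present.append(member.id)

    # ------------------------------------------------------------------
    def _hash_config(self) -> str:
        payload = json.dumps(
            {
                "scenario": self.scenario.to_dict(),
                "workload": {
                    "shape": self.workload.shape,
                    "amplitude": self.workload.amplitude,
                    "duration": self.workload.duration,
                    "period": self.workload.period,
                },
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def _build_shift_events(self) -> list[tuple[int, int, str]]:
        """(tick, kind, staff): kind 0 = shift start, 1 = shift end.

        Starts sort before ends at the same tick, so a relieving professional
        is on post the same tick their predecessor leaves."""
        events = []
        h48 = 48 * TICKS_PER_HOUR
        h12 = 12 * TICKS_PER_HOUR
        for member in self.scenario.staff:
            offset = member.roster.offset_hours * TICKS_PER_HOUR
            start = offset - h48
            while start <= self.duration_ticks:
                if start > 0:
                    events.append((start, 0, member.id))
                end = start + h12
                if 0 < end <= self.duration_ticks:
                    events.append((end, 1, member.id))
                start += h48
        events.sort()
        return events

    # ------------------------------------------------------------------
    def _route(self, stage_name: str) -> str:
        """Follow the flow graph from a completed stage to the next physical
        stage or EXIT, resolving virtual branch points along the way."""
        current = stage_name
        while True:
            targets, cum = self._route_table[current]
            r = self.rng.random()
            current = targets[bisect_right(cum, r)]
            if current == EXIT:
                return EXIT
            if self._stage[current].room is not None:
                return current

    def _enqueue(self, patient_id: int, stage_name: str, now: int) -> None:
        room = self.rooms[self._stage[stage_name].room]
        room.queue.append((patient_id, now, stage_name))
        room.cycle_arrivals += 1

    def _admit(self, now: int) -> None:
        pid = self._next_patient
        self._next_patient += 1
        self.patients[pid] = PatientRecord(pid)
        self.entered += 1
        self._enqueue(pid, self.scenario.entry_stage, now)

    def _sample_recipe(self, stage: Stage) -> int:
        room = self.scenario.rooms[stage.room]
        minutes = 0.0
        for name in stage.recipe:
            at = room.attendance(name)
            if at.upper == at.lower:
                minutes += at.lower
            else:
                minutes += self.rng.triangular(at.lower, at.mode, at.upper)
        return max(1, int(round(minutes * TICKS_PER_MINUTE)))

    def act_estimate(self, room_name: str) -> float:
        """Trailing mean of recently completed care durations, or the static
        triangular-mean fallback while the room has no history."""
        recent = self.rooms[room_name].recent_durations
        if recent:
            return float(np.mean(recent))
        return self._fallback_act[room_name]

    # ------------------------------------------------------------------
    # tick phases
    # ------------------------------------------------------------------
    def _complete_services(self, now: int) -> None:
        heap = self._service_heap
        while heap and heap[0][0] <= now:
            end, _seq, room_name, pid = heapq.heappop(heap)
            room = self.rooms[room_name]
            staff_id = room.server_of.pop(pid, None)
            if staff_id is None:  # pragma: no cover - defensive
                continue
            room.busy.pop(staff_id, None)
            patient = self.patients[pid]
            stage_name, rname, enq, start, _ = patient.visits[-1]
            patient.visits[-1] = (stage_name, rname, enq, start, end)
            duration_min = (end - start) / TICKS_PER_MINUTE
            room.cycle_durations.append(duration_min)
            room.recent_durations.append(duration_min)
            if self.collect_visits:
                self.log.visits.append((pid, stage_name, rname, enq, start, end))

            self._after_service_staff(staff_id, room, now)

            nxt = self._route(stage_name)
            if nxt == EXIT:
                patient.exit_tick = now
                self.exited += 1
            else:
                self._enqueue(pid, nxt, now)

    def _after_service_staff(self, staff_id: str, room: RoomState, now: int) -> None:
        st = self.staffing.states[staff_id]
        if st.pending_shift_end:
            st.pending_shift_end = False
            room.present.remove(staff_id)
            self.staffing.end_shift(staff_id, now)
        elif st.pending_move is not None:
            order = st.pending_move
            room.present.remove(staff_id)
            eta = now + SimClock.minutes_to_ticks(self.scenario.reallocation_minutes)
            self.staffing.begin_transit(
                staff_id, REALLOCATE, order.to_room, now, eta,
                st.overtime, self._cycle_index(now),
            )
            heapq.heappush(self._transit_heap, (eta, self._next_seq(), staff_id))
        elif st.pending_dealloc or (
            st.status == "overtime" and st.dealloc_deadline is not None
            and now >= st.dealloc_deadline
        ):
            room.present.remove(staff_id)
            self.staffing.deallocate(staff_id, now, self._cycle_index(now))

    def _land_transits(self, now: int) -> None:
        heap = self._transit_heap
        while heap and heap[0][0] <= now:
            _eta, _seq, staff_id = heapq.heappop(heap)
            st = self.staffing.states[staff_id]
            if st.transit is None:  # pragma: no cover - defensive
                continue
            kind, to_room, _e, overtime = st.transit
            self.rooms[to_room].inbound -= 1
            if overtime and st.dealloc_deadline is not None and now >= st.dealloc_deadline:
                st.transit = None
                st.status = "overtime"
                self.staffing.deallocate(staff_id, now, self._cycle_index(now))
                continue
            if not overtime:
                # a reallocation landing after the rostered shift expired
                if not self.staffing.on_duty(staff_id, now):
                    st.transit = None
                    st.status = "on_shift"
                    self.staffing.end_shift(staff_id, now)
                    continue
            room = self.staffing.land(staff_id, now)
            self.rooms[room].present.append(staff_id)
            if overtime and kind == ALLOCATE:
                heapq.heappush(self._forced_heap, (st.dealloc_deadline, staff_id))

    def _apply_shift_events(self, now: int) -> None:
        events = self._shift_events
        while self._shift_ptr < len(events) and events[self._shift_ptr][0] <= now:
            _t, kind, staff_id = events[self._shift_ptr]
            self._shift_ptr += 1
            st = self.staffing.states[staff_id]
            if kind == 0:
                if st.status == "off":
                    room = self.staffing.begin_shift(staff_id, now)
                    self.rooms[room].present.append(staff_id)
            else:
                if st.status == "on_shift":
                    room = self.rooms[st.room] if st.room is not None else None
                    if room is not None and staff_id in room.busy:
                        successor = self._handover_target(st, room, now)
                        if successor is not None:
                            entry = room.busy.pop(staff_id)
                            room.busy[successor] = entry
                            room.server_of[entry[0]] = successor
                            room.present.remove(staff_id)
                            self.staffing.end_shift(staff_id, now)
                        else:
                            # finish the current patient, then go home
                            st.pending_shift_end = True
                    else:
                        if room is not None:
                            room.present.remove(staff_id)
                        self.staffing.end_shift(staff_id, now)
                # in-transit staff are retired on landing instead
        heap = self._forced_heap
        while heap and heap[0][0] <= now:
            _t, staff_id = heapq.heappop(heap)
            st = self.staffing.states[staff_id]
            if st.status == "overtime" and staff_id not in self.rooms[st.room].busy:
                self.rooms[st.room].present.remove(staff_id)
                self.staffing.deallocate(staff_id, now, self._cycle_index(now))
            # if serving, the post-service hook deallocates (cannot happen
            # under the no-overrun start rule, kept as a safety net)

    def _handover_target(
        self, st, room: RoomState, now: int
    ) -> Optional[str]:
        """The relieving post-mate who takes over an in-progress service at a
        rostered shift change: same post, just on duty, idle in this room."""
        for cand in room.present:
            cst = self.staffing.states[cand]
            if (
                cand not in room.busy
                and cst.status == "on_shift"
                and cst.member.roster.post == st.member.roster.post
                and not cst.pending_dealloc
                and cst.pending_move is None
            ):
                return cand
        return None

    def _admit_arrivals(self, now: int) -> None:
        t_min = (now % SimClock.minutes_to_ticks(self.workload.duration)) \
            / TICKS_PER_MINUTE
        rate = rate_at(self.workload, t_min)
        count, self.accumulator = integer_arrivals(rate, self.accumulator)
        for _ in range(count):
            self._admit(now)

    def _start_services(self, now: int) -> None:
        for room in self.rooms.values():
            if not room.queue:
                continue
            capacity = min(room.active, room.config.station_limit) - len(room.busy)
            if capacity <= 0:
                continue
            free = [
                s for s in room.present
                if s not in room.busy
                and self.staffing.states[s].pending_move is None
                and not self.staffing.states[s].pending_dealloc
            ]
            while room.queue and capacity > 0 and free:
                pid, enq, stage_name = room.queue[0]
                dur = self._sample_recipe(self._stage[stage_name])
                server = None
                for s in free:
                    st = self.staffing.states[s]
                    if st.status == "on_shift" and st.room == st.home_room:
                        # the relieving post-mate takes over at shift change
                        server = s
                        break
                    if now + dur <= self.staffing.allowed_service_end(s, now):
                        server = s
                        break
                if server is None:
                    break  # FIFO head must wait for the relieving shift
                room.queue.popleft()
                free.remove(server)
                capacity -= 1
                end = now + dur
                room.busy[server] = (pid, end)
                room.server_of[pid] = server
                self.patients[pid].visits.append(
                    (stage_name, room.name, enq, now, end)
                )
                heapq.heappush(
                    self._service_heap, (end, self._next_seq(), room.name, pid)
                )
                wait_min = (now - enq) / TICKS_PER_MINUTE
                hour = now // TICKS_PER_HOUR
                if hour < self.log.n_hours:
                    if wait_min > self.log.hourly_max_wait[hour]:
                        self.log.hourly_max_wait[hour] = wait_min
                    self.log.hourly_wait_count[hour] += 1

    def _cycle_index(self, now: int) -> int:
        return now // self.cycle_ticks

    def _roll_cycle(self, now: int) -> None:
        for name, room in self.rooms.items():
            durations = room.cycle_durations
            act_value = float(np.mean(durations)) if durations else 0.0
            wait = (
                current_wait(room, self.act_estimate(name))
                if room.active else math.inf
            )
            self.store[name].append_cycle(
                act_value,
                float(room.cycle_arrivals),
                float(room.queue_len),
                room.na_sum / self.cycle_ticks,
                wait if math.isfinite(wait) else -1.0,
            )
            room.cycle_durations = []
            room.cycle_arrivals = 0
            room.na_sum = 0

    def _enact_orders(self, orders: Sequence[MovementOrder], now: int) -> None:
        cycle = self._cycle_index(now)
        realloc_ticks = SimClock.minutes_to_ticks(self.scenario.reallocation_minutes)
        alloc_ticks = SimClock.minutes_to_ticks(self.scenario.allocation_minutes)
        for order in orders:
            ok, why = self.staffing.validate_order(order, now, cycle)
            if ok and order.kind in (REALLOCATE, ALLOCATE):
                dest = self.rooms[order.to_room]
                if dest.active + dest.inbound >= dest.config.station_limit:
                    ok, why = False, staffing_mod.Refusal(
                        "capacity", "destination at station limit"
                    )
            if ok and order.kind == REALLOCATE:
                origin = self.rooms[order.from_room]
                if origin.active <= 1:
                    ok, why = False, staffing_mod.Refusal(
                        "floor", "origin room would be left unstaffed"
                    )
                else:
                    st = self.staffing.states[order.staff_id]
                    if st.status == "on_shift":
                        remaining = self.staffing.shift_end(
                            order.staff_id, now
                        ) - (now + realloc_ticks)
                        if remaining < self.cycle_ticks:
                            ok, why = False, staffing_mod.Refusal(
                                "shift-end", "too little shift left after transit"
                            )
            if not ok:
                self.staffing.log_movement(now, order, f"rejected:{why.rule}")
                self.log.rejected_orders += 1
                continue

            if order.kind == REALLOCATE:
                st = self.staffing.states[order.staff_id]
                room = self.rooms[order.from_room]
                self.rooms[order.to_room].inbound += 1
                if order.staff_id in room.busy:
                    st.pending_move = order
                    self.staffing.log_movement(now, order, "enacted:after-patient")
                else:
                    room.present.remove(order.staff_id)
                    eta = now + realloc_ticks
                    self.staffing.begin_transit(
                        order.staff_id, REALLOCATE, order.to_room, now, eta,
                        st.overtime, cycle,
                    )
                    heapq.heappush(
                        self._transit_heap, (eta, self._next_seq(), order.staff_id)
                    )
                    self.staffing.log_movement(now, order, "enacted", eta)
            elif order.kind == ALLOCATE:
                eta = now + alloc_ticks
                self.rooms[order.to_room].inbound += 1
                self.staffing.begin_transit(
                    order.staff_id, ALLOCATE, order.to_room, now, eta, True, cycle
                )
                heapq.heappush(
                    self._transit_heap, (eta, self._next_seq(), order.staff_id)
                )
                self.staffing.log_movement(now, order, "enacted", eta)
            else:  # deallocate
                st = self.staffing.states[order.staff_id]
                room = self.rooms[st.room]
                if order.staff_id in room.busy:
                    st.pending_dealloc = True
                    self.staffing.log_movement(now, order, "enacted:after-patient")
                else:
                    room.present.remove(order.staff_id)
                    self.staffing.deallocate(order.staff_id, now, cycle)
                    self.staffing.log_movement(now, order, "enacted", now)

    def _next_seq(self) -> int:
        self._seq += 1
        return self._seq

    # ------------------------------------------------------------------
    def step(self, now: int) -> None:
        """Advance one tick (phases as documented in the module docstring)."""
        self._complete_services(now)
        self._land_transits(now)
        self._apply_shift_events(now)
        self._admit_arrivals(now)
        self._start_services(now)

        total_active = 0
        for room in self.rooms.values():
            a = room.active
            room.na_sum += a
            total_active += a
        hour = now // TICKS_PER_HOUR
        if hour < self.log.n_hours:
            log = self.log
            log.hourly_active_sum[hour] += total_active
            if total_active < log.hourly_active_min[hour]:
                log.hourly_active_min[hour] = total_active
            if total_active > log.hourly_active_max[hour]:
                log.hourly_active_max[hour] = total_active
            log.hourly_onshift_sum[hour] += self.staffing.on_shift_count
            log.hourly_overtime_sum[hour] += self.staffing.overtime_count

        if (now + 1) % self.cycle_ticks == 0:
            self._roll_cycle(now)
            if self.controller is not None:
                orders = self.controller.orders(self, self._cycle_index(now), now)
                self._enact_orders(orders, now)

    def run(self) -> SimulationLog:
        for now in range(self.duration_ticks):
            self.step(now)
            self.clock.advance()
        self.log.entered = self.entered
        self.log.exited = self.exited
        self.log.in_system_at_end = self.entered - self.exited
        self.log.movements = self.staffing.movement_log
        return self.log


def run_scenario(
    scenario: ScenarioConfig,
    workload: WorkloadProfile,
    controller_mode: str = "none",
    seed: int = 0,
    duration_minutes: float = 7 * 1440.0,
    upper: Optional[float] = None,
    lower: Optional[float] = None,
    collect_visits: bool = True,
) -> SimulationLog:
    """Run one scenario end to end.

    ``controller_mode``: ``"none"`` for static staffing, ``"reactive"`` for
    threshold-triggered elasticity, ``"proactive"`` for forecast-driven
    elasticity.  ``upper``/``lower`` override the waiting-time thresholds in
    minutes (defaults: 70%/30% of the 30-minute maximum load for reactive,
    30 min / 9 min for proactive).
    """
    if controller_mode == "none":
        controller = None
    elif controller_mode == "reactive":
        from .controller_reactive import ReactiveController

        controller = ReactiveController(upper=upper, lower=lower)
    elif controller_mode == "proactive":
        from .controller_proactive import ProactiveController

        controller = ProactiveController(upper=upper, lower=lower)
    else:
        raise ValueError(f"unknown controller mode {controller_mode!r}")
    sim = Simulation(
        scenario, workload, controller=controller, seed=seed,
        duration_minutes=duration_minutes, collect_visits=collect_visits,
    )
    return sim.run()
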