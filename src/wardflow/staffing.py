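"""Staff availability rules and movement bookkeeping.

Every professional follows a Brazilian 12 h-on / 36 h-off roster.  Off-shift
staff may be summoned (an *allocation*, paid as overtime at 1.5x), on-duty
staff may be *reallocated* between rooms, and overtime staff may be
*deallocated*.  Four labor rules bound overtime:

* Rule 1 -- a professional must have rested at least 11 consecutive hours
  before becoming available for allocation.
* Rule 2 -- continuous work never exceeds 12 hours.
* Rule 3 -- an allocated professional must be deallocated no later than 11
  hours before their next rostered shift.
* Rule 4 -- every professional keeps at least one uninterrupted 36-hour rest
  period inside each (rolling, simulation-aligned) week.

Rules 2 and 3 are enforced through a *deallocation deadline* fixed when the
overtime stint begins; the engine never lets a professional start a service
that would finish past their deadline (or past their rostered shift end), so
the bounds hold at every simulated instant.  Rule 4 is a feasibility check at
allocation time: the stint, even if it runs to its deadline, must leave a
36-hour gap somewhere in the week given all known commitments.

A cooldown rule damps hysteresis: a resource reallocated from room A to room
B in cycle *k* cannot be ordered back to A in cycle *k+1*, and a professional
cannot bounce between allocation and deallocation on consecutive cycles.  A
deallocated professional is not allocated again within the same 12-hour
shift window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .scenario import ScenarioConfig, StaffMember

REALLOCATE = "reallocate"
ALLOCATE = "allocate"
DEALLOCATE = "deallocate"


@dataclass(frozen=True)
class MovementOrder:
    staff_id: str
    kind: str  # reallocate | allocate | deallocate
    from_room: Optional[str]
    to_room: Optional[str]
    issue_tick: int
    eta_tick: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in (REALLOCATE, ALLOCATE, DEALLOCATE):
            raise ValueError(f"unknown movement kind {self.kind!r}")


@dataclass
class Refusal:
    rule: str
    detail: str

    def __bool__(self) -> bool:  # a refusal is falsy as an availability answer
        return False


@dataclass
class AllocationState:
    """Runtime labor-law bookkeeping for one professional."""

    member: StaffMember
    home_room: str
    status: str = "off"  # off | on_shift | overtime | transit
    room: Optional[str] = None
    overtime: bool = False
    current_work_start: Optional[int] = None
    last_work_end: int = -(10**9)
    dealloc_deadline: Optional[int] = None
    work_intervals: list[tuple[int, int]] = field(default_factory=list)
    transit: Optional[tuple[str, str, int, bool]] = None  # kind, to, eta, overtime
    pending_move: Optional[MovementOrder] = None
    pending_dealloc: bool = False
    pending_shift_end: bool = False
    last_realloc: Optional[tuple[str, int]] = None  # (origin room, cycle)
    last_alloc_cycle: Optional[int] = None
    last_dealloc_cycle: Optional[int] = None
    last_dealloc_window: Optional[int] = None


class StaffingState:
    """Tracks every professional's legal availability and movements."""

    def __init__(self, scenario: ScenarioConfig, ticks_per_minute: int = 6):
        self.scenario = scenario
        self.tpm = ticks_per_minute
        self.tph = 60 * ticks_per_minute
        self.h11 = 11 * self.tph
        self.h12 = 12 * self.tph
        self.h36 = 36 * self.tph
        self.h48 = 48 * self.tph
        self.week = 168 * self.tph
        self.states: dict[str, AllocationState] = {}
        for member in scenario.staff:
            st = AllocationState(member=member, home_room=scenario.home_room(member))
            offset = member.roster.offset_hours * self.tph
            prev_end = offset - 36 * self.tph  # end of the previous rostered shift
            st.last_work_end = prev_end
            st.work_intervals.append((prev_end - self.h12, prev_end))
            self.states[member.id] = st
        self.movement_log: list[dict] = []
        self.on_shift_count = 0
        self.overtime_count = 0  # allocated or in allocation transit

    # -- roster arithmetic -------------------------------------------------
    def shift_phase(self, staff_id: str, t: int) -> int:
        offset = self.states[staff_id].member.roster.offset_hours * self.tph
        return (t - offset) % self.h48

    def on_duty(self, staff_id: str, t: int) -> bool:
        return self.shift_phase(staff_id, t) < self.h12

    def shift_end(self, staff_id: str, t: int) -> int:
        """End tick of the rostered shift containing ``t`` (must be on duty)."""
        return t + (self.h12 - self.shift_phase(staff_id, t))

    def next_shift_start(self, staff_id: str, t: int) -> int:
        phase = self.shift_phase(staff_id, t)
        return t + (self.h48 - phase)

    # -- Rules 1-4 ---------------------------------------------------------
    def available_for_allocation(
        self, staff_id: str, t: int, cycle: Optional[int] = None
    ) -> tuple[bool, Optional[Refusal]]:
        st = self.states[staff_id]
        if st.status != "off":
            return False, Refusal("status", f"{staff_id} is {st.status}")
        if self.on_duty(staff_id, t):
            return False, Refusal("status", "on rostered duty")
        window = t // self.h12
        if st.last_dealloc_window == window:
            return False, Refusal(
                "same-shift", "already deallocated in this shift window"
            )
        if cycle is not None and st.last_dealloc_cycle == cycle - 1:
            return False, Refusal("cooldown", "deallocated in the previous cycle")
        # rest since the later of the recorded work end and the end of the
        # most recent rostered shift (robust without an engine-driven history)
        last_rostered_end = t - (self.shift_phase(staff_id, t) - self.h12)
        rest_anchor = max(st.last_work_end, last_rostered_end)
        if t - rest_anchor < self.h11:
            return False, Refusal("rule1", "rested less than 11 h")
        eta = t + int(round(self.scenario.allocation_minutes * self.tpm))
        deadline = self.dealloc_deadline_for(staff_id, t)
        min_stint = int(round(self.scenario.cycle_minutes * self.tpm))
        if deadline < eta + min_stint:
            return False, Refusal(
                "rule3", "cannot serve a useful stint and still rest 11 h "
                "before the next rostered shift"
            )
        if not self._rule4_feasible(st, t, deadline):
            return False, Refusal("rule4", "would break the weekly 36 h rest")
        return True, None

    def dealloc_deadline_for(self, staff_id: str, t: int) -> int:
        """Latest tick an overtime stint starting at ``t`` may run to."""
        next_shift = self.next_shift_start(staff_id, t)
        return min(t + self.h12, next_shift - self.h11)

    def _rule4_feasible(self, st: AllocationState, t: int, deadline: int) -> bool:
        week_start = (t // self.week) * self.week
        week_end = week_start + self.week
        busy: list[tuple[int, int]] = []
        # rostered shifts overlapping the week
        offset = st.member.roster.offset_hours * self.tph
        k0 = (week_start - offset) // self.h48 - 1
        k = k0
        while True:
            start = offset + k * self.h48
            if start >= week_end:
                break
            end = start + self.h12
            if end > week_start:
                busy.append((max(start, week_start), min(end, week_end)))
            k += 1
        for start, end in st.work_intervals:
            if end > week_start and start < week_end:
                busy.append((max(start, week_start), min(end, week_end)))
        busy.append((max(t, week_start), min(deadline, week_end)))
        busy.sort()
        merged: list[list[int]] = []
        for start, end in busy:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        gaps = []
        prev = week_start
        for start, end in merged:
            gaps.append(start - prev)
            prev = max(prev, end)
        gaps.append(week_end - prev)
        return max(gaps) >= self.h36

    # -- cooldown ----------------------------------------------------------
    def cooldown_blocked(self, staff_id: str, to_room: str, cycle: int) -> bool:
        """True iff sending this resource to ``to_room`` now would return it
        to the room it left in the immediately preceding monitoring cycle."""
        last = self.states[staff_id].last_realloc
        return last is not None and last == (to_room, cycle - 1)

    def dealloc_cooldown_blocked(self, staff_id: str, cycle: int) -> bool:
        last = self.states[staff_id].last_alloc_cycle
        return last is not None and last == cycle - 1

    # -- order validation --------------------------------------------------
    def validate_order(
        self, order: MovementOrder, t: int, cycle: int
    ) -> tuple[bool, Optional[Refusal]]:
        st = self.states.get(order.staff_id)
        if st is None:
            return False, Refusal("unknown", f"no staff {order.staff_id!r}")
        if order.kind == REALLOCATE:
            if st.room != order.from_room or st.status not in ("on_shift", "overtime"):
                return False, Refusal("status", "not serving the origin room")
            if st.pending_move is not None or st.pending_dealloc:
                return False, Refusal("status", "already ordered to move")
            room = self.scenario.rooms[order.to_room]
            if room.required_specialty not in st.member.specialties:
                return False, Refusal(
                    "specialty",
                    f"{order.staff_id} lacks {room.required_specialty!r}",
                )
            if self.cooldown_blocked(order.staff_id, order.to_room, cycle):
                return False, Refusal("cooldown", "returned too soon to origin room")
            return True, None
        if order.kind == ALLOCATE:
            room = self.scenario.rooms[order.to_room]
            if room.required_specialty not in st.member.specialties:
                return False, Refusal(
                    "specialty",
                    f"{order.staff_id} lacks {room.required_specialty!r}",
                )
            if self.cooldown_blocked(order.staff_id, order.to_room, cycle):
                return False, Refusal("cooldown", "returned too soon to origin room")
            return self.available_for_allocation(order.staff_id, t, cycle)
        # deallocate
        if st.status != "overtime":
            return False, Refusal(
                "status", "only overtime-allocated staff are deallocated"
            )
        if st.pending_dealloc or st.pending_move is not None:
            return False, Refusal("status", "already ordered to move")
        if self.dealloc_cooldown_blocked(order.staff_id, cycle):
            return False, Refusal("cooldown", "allocated in the previous cycle")
        return True, None

    # -- state transitions (driven by the engine) --------------------------
    def log_movement(self, t: int, order: MovementOrder, outcome: str,
                     eta: Optional[int] = None) -> None:
        self.movement_log.append(
            {
                "tick": t,
                "staff": order.staff_id,
                "kind": order.kind,
                "from": order.from_room,
                "to": order.to_room,
                "eta": eta if eta is not None else order.eta_tick,
                "outcome": outcome,
            }
        )

    def begin_shift(self, staff_id: str, t: int) -> str:
        st = self.states[staff_id]
        st.status = "on_shift"
        st.room = st.home_room
        st.overtime = False
        st.current_work_start = t
        st.dealloc_deadline = None
        self.on_shift_count += 1
        return st.home_room

    def end_shift(self, staff_id: str, t: int) -> None:
        st = self.states[staff_id]
        st.status = "off"
        st.room = None
        self._close_work(st, t)
        self.on_shift_count -= 1

    def begin_transit(
        self, staff_id: str, kind: str, to_room: str, depart: int, eta: int,
        overtime: bool, cycle: int,
    ) -> None:
        st = self.states[staff_id]
        if kind == ALLOCATE:
            st.current_work_start = depart  # paid from the summons onward
            st.dealloc_deadline = self.dealloc_deadline_for(staff_id, depart)
            st.last_alloc_cycle = cycle
            self.overtime_count += 1
        elif st.room is not None:
            st.last_realloc = (st.room, cycle)
        st.status = "transit"
        st.room = None
        st.transit = (kind, to_room, eta, overtime or kind == ALLOCATE)
        st.pending_move = None

    def land(self, staff_id: str, t: int) -> str:
        st = self.states[staff_id]
        kind, to_room, _eta, overtime = st.transit
        st.transit = None
        st.room = to_room
        st.overtime = overtime
        st.status = "overtime" if overtime else "on_shift"
        return to_room

    def deallocate(self, staff_id: str, t: int, cycle: Optional[int]) -> None:
        st = self.states[staff_id]
        st.status = "off"
        st.room = None
        st.pending_dealloc = False
        st.dealloc_deadline = None
        self._close_work(st, t)
        self.overtime_count -= 1
        st.last_dealloc_window = t // self.h12
        if cycle is not None:
            st.last_dealloc_cycle = cycle

    def _close_work(self, st: AllocationState, t: int) -> None:
        if st.current_work_start is not None:
            st.work_intervals.append((st.current_work_start, t))
        st.current_work_start = None
        st.last_work_end = t
        st.overtime = False

    # -- queries used by the engine and controllers ------------------------
    def allowed_service_end(self, staff_id: str, t: int) -> int:
        """Latest tick a service started now by this professional may end."""
        st = self.states[staff_id]
        if st.status == "overtime":
            return st.dealloc_deadline
        if st.status == "on_shift":
            return self.shift_end(staff_id, st.current_work_start or t)
        return t

    def _untouched_36h_gaps(self, st: AllocationState, t: int,
                            extra: Optional[tuple[int, int]] = None) -> int:
        """Complete 36 h rest gaps of the current week still fully free."""
        week_start = (t // self.week) * self.week
        week_end = week_start + self.week
        offset = st.member.roster.offset_hours * self.tph
        intervals = list(st.work_intervals)
        if st.current_work_start is not None:
            intervals.append((st.current_work_start, max(t, st.current_work_start)))
        if extra is not None:
            intervals.append(extra)
        count = 0
        k = (week_start - offset) // self.h48 - 1
        while True:
            shift_end = offset + k * self.h48 + self.h12
            gap = (shift_end, shift_end + self.h36)
            k += 1
            if gap[0] >= week_end:
                break
            if gap[0] < week_start or gap[1] > week_end:
                continue
            if all(e <= gap[0] or s >= gap[1] for s, e in intervals):
                count += 1
        return count

    def external_pool(
        self, specialty: str, t: int, cycle: int
    ) -> list[str]:
        """Off-shift professionals legally available for allocation, holding
        the required specialty.

        Ordered to conserve the weekly 36 h rest budget: professionals whose
        candidate stint would fall inside an already-broken rest gap come
        first, so untouched gaps are kept in reserve for later in the week;
        ties resolve by id for determinism.
        """
        pool = []
        for staff_id in sorted(self.states):
            st = self.states[staff_id]
            if specialty not in st.member.specialties:
                continue
            ok, _why = self.available_for_allocation(staff_id, t, cycle)
            if ok:
                stint = (t, self.dealloc_deadline_for(staff_id, t))
                gap_cost = self._untouched_36h_gaps(st, t) - \
                    self._untouched_36h_gaps(st, t, extra=stint)
                pool.append((gap_cost, staff_id))
        pool.sort()
        return [staff_id for _cost, staff_id in pool]

    def movements_frame(self):
        import pandas as pd

        return pd.DataFrame.from_records(
            self.movement_log,
            columns=["tick", "staff", "kind", "from", "to", "eta", "outcome"],
        )
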