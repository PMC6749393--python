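"""Threshold-triggered (reactive) elasticity controller.

Each monitoring cycle the measured waiting-time estimate of every room --
queue length times recent average care time, divided by the attendants in
parallel -- is compared against an upper and a lower threshold (percentages
of the 30-minute statutory maximum load).  A room above the upper bound
needs attendants; a room below the lower bound can spare them.  The
hospital-level pass reconciles the per-room deltas exactly as the proactive
controller does -- release overtime staff when the whole hospital is quiet,
fill needy rooms by reallocating from surplus rooms first (the cheaper
action), then summon off-shift staff for whatever remains -- only the
trigger differs: measured state here, forecasts there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .controller_proactive import hospital_cycle_orders
from .equations import hres
from .scenario import MAX_LOAD_MINUTES
from .staffing import MovementOrder

DEFAULT_UPPER = 0.7 * MAX_LOAD_MINUTES  # 21 min
DEFAULT_LOWER = 0.3 * MAX_LOAD_MINUTES  # 9 min


@dataclass(frozen=True)
class RoomDelta:
    """Signed attendant need (+) or surplus (-) of one room."""

    room: str
    q: int


def room_delta_reactive(
    room_state, act_estimate: float,
    upper: float = DEFAULT_UPPER, lower: float = DEFAULT_LOWER,
) -> RoomDelta:
    """Measured-state attendant delta for one room.

    Above the upper threshold: the smallest ``n >= 1`` such that
    ``queue * ACT / (a + n)`` falls to the threshold, capped at the room's
    station limit.  Below the lower threshold: minus the largest number of
    attendants whose removal keeps the estimated wait under the threshold,
    never dropping below one attendant.  Attendants already in transit
    toward the room count as supply, so pending orders are not re-issued.
    """
    queue = room_state.queue_len
    a = room_state.active + room_state.inbound
    limit = room_state.config.station_limit

    def wait(a_prime: int) -> float:
        return hres(queue * act_estimate, a_prime)

    q = 0
    if wait(a) > upper:
        a_prime = a
        while a_prime < limit and wait(a_prime) > upper:
            q += 1
            a_prime = a + q
    elif wait(a) < lower:
        while a - (q + 1) >= 1 and wait(a - (q + 1)) < lower:
            q += 1
        q = -q
    return RoomDelta(room_state.name, q)


class ReactiveController:
    """Threshold-based elasticity: act after a threshold is crossed."""

    name = "reactive"

    def __init__(
        self, upper: Optional[float] = None, lower: Optional[float] = None
    ):
        self.upper = DEFAULT_UPPER if upper is None else upper
        self.lower = DEFAULT_LOWER if lower is None else lower
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")
        self._prev_quiet = False

    def orders(self, sim, cycle: int, now: int) -> list[MovementOrder]:
        deltas: dict[str, int] = {}
        quiet = True
        for name, room in sim.rooms.items():
            act_est = sim.act_estimate(name)
            delta = room_delta_reactive(room, act_est, self.upper, self.lower)
            deltas[name] = delta.q
            measured = (
                hres(room.queue_len * act_est, room.active)
                if room.active else math.inf
            )
            if not measured < self.lower:
                quiet = False
        all_quiet = quiet and self._prev_quiet
        self._prev_quiet = quiet
        return hospital_cycle_orders(sim, cycle, now, deltas, all_quiet)


def control_cycle_reactive(
    sim, cycle: int, now: int,
    upper: Optional[float] = None, lower: Optional[float] = None,
) -> list[MovementOrder]:
    """One-shot functional form of :class:`ReactiveController`."""
    return ReactiveController(upper, lower).orders(sim, cycle, now)
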