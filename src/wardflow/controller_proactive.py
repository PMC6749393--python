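"""Forecast-driven (proactive) elasticity controller.

Each monitoring cycle, per-room ARIMA forecasts of the average care time and
of incoming patients are combined into the proactive elastic speedup
``PHRES(r, a) = (ACT' * ENP') / a`` -- the predicted wait over a future
window were the room staffed with ``a`` attendants.  The room-level rule
searches the attendant delta ``n`` that brings ``PHRES(r, a+n)`` back inside
the ``[lower, upper]`` waiting-time band, bounded by the room's care-station
limit below and by a floor of one attendant above.

Hospital-wide, deltas are reconciled greedily: overtime staff are released
when the whole hospital is predicted quiet, then needy rooms draw attendants
from surplus rooms through an adapted dynamic list-scheduling discipline
(take one attendant from the room with most spare attendants holding the
required specialty, re-sort, repeat), and only unmet need is covered by
summoning off-shift professionals, which costs overtime.  The forecast
horizon runs from one reallocation delay to one allocation delay plus a
cycle ahead, so decisions cover the lead time of the slowest action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .equations import ForecastEngine, ect, hres
from .staffing import ALLOCATE, DEALLOCATE, REALLOCATE, MovementOrder

DEFAULT_UPPER = 30.0  # minutes: the statutory maximum waiting time
DEFAULT_LOWER = 9.0   # minutes: 30% of the maximum load


def room_delta_predictive(
    a: int, ect_prime: float, upper: float, lower: float, limit: int
) -> int:
    """Signed attendant delta bringing the predicted wait inside the band.

    Mirrors the room-level predictive loop: while the predicted wait with
    ``a'`` attendants exceeds ``upper`` and ``a' < limit``, add one; while it
    is below ``lower`` and ``a' > 0``, remove one.  May return ``-a`` (an
    idle-forecast room); the hospital-level step keeps a one-attendant floor
    when enacting.
    """
    n = 0
    a_prime = a
    if hres(ect_prime, a) > upper:
        while a_prime < limit and hres(ect_prime, a_prime) > upper:
            n += 1
            a_prime = a + n
    elif hres(ect_prime, a) < lower:
        while a_prime > 0 and hres(ect_prime, a_prime) < lower:
            n -= 1
            a_prime = a + n
    return n


def list_schedule_reallocation(
    needy_room: str,
    free_by_room: Sequence[tuple[str, Sequence[str]]],
    demand: int,
) -> list[tuple[str, str]]:
    """Greedy balanced reallocation adapted from dynamic list scheduling.

    ``free_by_room`` lists each donor room with the attendants it can spare
    (already filtered to those holding the needy room's specialty and not
    cooldown-blocked), sorted by spare count descending.  One attendant is
    taken from the head room, the list is re-sorted, and so on until the
    demand is met or nobody eligible remains.  Ties favour the room that
    donated most recently, then the room latest in the list -- the ordering
    that reproduces the reference walkthrough of this discipline.
    """
    pools: list[tuple[str, list[str]]] = [
        (name, list(staff)) for name, staff in free_by_room
    ]
    orig_index = {name: i for i, (name, _) in enumerate(pools)}
    last_donated = {name: -1 for name, _ in pools}
    assignments: list[tuple[str, str]] = []
    rnd = 0
    while len(assignments) < demand:
        candidates = [(name, staff) for name, staff in pools if staff]
        if not candidates:
            break
        candidates.sort(
            key=lambda item: (
                -len(item[1]),
                -last_donated[item[0]],
                -orig_index[item[0]],
            )
        )
        name, staff = candidates[0]
        assignments.append((name, staff.pop(0)))
        last_donated[name] = rnd
        rnd += 1
    return assignments


# ---------------------------------------------------------------------------
# Hospital-level orchestration (shared with the reactive controller)
# ---------------------------------------------------------------------------

def hospital_cycle_orders(
    sim, cycle: int, now: int, deltas: dict[str, int], all_quiet: bool
) -> list[MovementOrder]:
    """Turn per-room deltas into a validated-ready order list.

    Order of operations: release overtime staff if the whole hospital is
    quiet; then fill every needy room by list-scheduling reallocation from
    surplus rooms; finally summon off-shift professionals for unmet need.
    Reallocation always precedes allocation -- it is the cheaper action.
    """
    staffing = sim.staffing
    dealloc_orders: list[MovementOrder] = []
    realloc_orders: list[MovementOrder] = []
    alloc_orders: list[MovementOrder] = []
    removed: set[str] = set()

    if all_quiet:
        for name, q in deltas.items():
            if q >= 0:
                continue
            room = sim.rooms[name]
            budget = min(-q, room.active - 1)
            overtime = [
                s for s in room.present
                if staffing.states[s].status == "overtime"
                and staffing.states[s].pending_move is None
                and not staffing.states[s].pending_dealloc
                and not staffing.dealloc_cooldown_blocked(s, cycle)
            ]
            overtime.sort(key=lambda s: (s in room.busy, s))  # idle first
            for s in overtime[:max(budget, 0)]:
                dealloc_orders.append(
                    MovementOrder(s, DEALLOCATE, name, None, now)
                )
                removed.add(s)

    # donor pools: surplus rooms may spare attendants down to a floor of one
    donor_staff: dict[str, list[str]] = {}
    donor_budget: dict[str, int] = {}
    for name, q in deltas.items():
        if q >= 0:
            continue
        room = sim.rooms[name]
        spare = [
            s for s in room.present
            if s not in removed
            and staffing.states[s].pending_move is None
            and not staffing.states[s].pending_dealloc
        ]
        spare.sort(key=lambda s: (s in room.busy, s))  # idle first
        removed_here = sum(1 for s in removed if s in room.present)
        donor_staff[name] = spare
        donor_budget[name] = max(
            0, min(-q - removed_here, room.active - removed_here - 1)
        )

    summoned: set[str] = set()
    needy = sorted(
        ((name, q) for name, q in deltas.items() if q > 0),
        key=lambda item: (-item[1], item[0]),
    )
    for name, q in needy:
        room = sim.rooms[name]
        specialty = room.config.required_specialty
        demand = min(q, room.config.station_limit - room.active - room.inbound)
        if demand <= 0:
            continue
        free_by_room = []
        for donor in sorted(donor_staff):
            budget = donor_budget[donor]
            if budget <= 0:
                continue
            eligible = [
                s for s in donor_staff[donor]
                if specialty in staffing.states[s].member.specialties
                and not staffing.cooldown_blocked(s, name, cycle)
            ][:budget]
            if eligible:
                free_by_room.append((donor, eligible))
        free_by_room.sort(key=lambda item: -len(item[1]))
        assignments = list_schedule_reallocation(name, free_by_room, demand)
        for donor, s in assignments:
            realloc_orders.append(MovementOrder(s, REALLOCATE, donor, name, now))
            donor_staff[donor].remove(s)
            donor_budget[donor] -= 1
            demand -= 1
        if demand > 0:
            pool = [
                s for s in staffing.external_pool(specialty, now, cycle)
                if s not in summoned
            ]
            for s in pool[:demand]:
                alloc_orders.append(MovementOrder(s, ALLOCATE, None, name, now))
                summoned.add(s)
    return dealloc_orders + realloc_orders + alloc_orders


# ---------------------------------------------------------------------------
# Controller
# ---------------------------------------------------------------------------

@dataclass
class RoomForecast:
    """Forecast inputs of one room for one control cycle."""

    act_prime: float
    enp_prime: float
    fallback: bool


def _fill_idle_cycles(series) -> "np.ndarray":
    """Carry the last observed average care time through idle cycles.

    A monitoring cycle in which no care completed stores a zero in the
    per-cycle series; for forecasting that zero is missing data, not a
    measurement of zero care time, so it is replaced by the last observation.
    """
    import numpy as np

    arr = np.asarray(series, dtype=float).copy()
    last = 0.0
    for i in range(len(arr)):
        if arr[i] > 0:
            last = arr[i]
        else:
            arr[i] = last
    return arr


class ProactiveController:
    """Predictive elasticity: act before thresholds are crossed."""

    name = "proactive"

    def __init__(
        self,
        upper: Optional[float] = None,
        lower: Optional[float] = None,
        forecaster: Optional[ForecastEngine] = None,
    ):
        self.upper = DEFAULT_UPPER if upper is None else upper
        self.lower = DEFAULT_LOWER if lower is None else lower
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")
        self.forecaster = forecaster if forecaster is not None else ForecastEngine()
        self._prev_quiet = False
        self.last_forecasts: dict[str, RoomForecast] = {}

    def _horizon_cycles(self, sim) -> int:
        sc = sim.scenario
        return max(
            1,
            math.ceil((sc.allocation_minutes + sc.cycle_minutes) / sc.cycle_minutes),
        )

    def room_forecast(self, sim, name: str, horizon: int) -> RoomForecast:
        """Predicted load of one room over the two action horizons.

        Two estimates of the patients needing care are formed and the worse
        one drives control: a *near* estimate at the reallocation lead (the
        current queue plus forecast arrivals over the next two cycles) and a
        *far* estimate at the allocation lead (the forecast queue length one
        allocation delay ahead, plus the arrivals of the following cycle).
        The far term is what lets external staff be summoned before the
        overload materializes; the near term keeps the controller honest
        about patients already waiting.
        """
        series = sim.store[name]
        act_fc = self.forecaster.predict(
            f"{name}:act", _fill_idle_cycles(series.act), horizon
        )
        nip_fc = self.forecaster.predict(f"{name}:nip", series.nip, horizon)
        nwp_fc = self.forecaster.predict(f"{name}:nwp", series.nwp, horizon)
        act_prime = act_fc.mean
        near = sim.rooms[name].queue_len + sum(nip_fc.values[:2])
        far = nwp_fc.values[-2] + nip_fc.values[-1] if horizon >= 2 else near
        enp_prime = max(near, far)
        if act_prime <= 0 and enp_prime > 0:
            # an idle-history room with patients present: fall back to the
            # measured trailing mean so the queue is not predicted free
            act_prime = sim.act_estimate(name)
        return RoomForecast(
            act_prime=act_prime,
            enp_prime=enp_prime,
            fallback=act_fc.fallback or nip_fc.fallback,
        )

    def orders(self, sim, cycle: int, now: int) -> list[MovementOrder]:
        horizon = self._horizon_cycles(sim)
        deltas: dict[str, int] = {}
        quiet = True
        self.last_forecasts = {}
        for name, room in sim.rooms.items():
            fc = self.room_forecast(sim, name, horizon)
            self.last_forecasts[name] = fc
            ect_prime = ect(fc.act_prime, fc.enp_prime)
            a_eff = room.active + room.inbound
            deltas[name] = room_delta_predictive(
                a_eff, ect_prime, self.upper, self.lower,
                room.config.station_limit,
            )
            if not hres(ect_prime, max(room.active, 1)) < self.lower:
                quiet = False
        all_quiet = quiet and self._prev_quiet
        self._prev_quiet = quiet
        return hospital_cycle_orders(sim, cycle, now, deltas, all_quiet)


def control_cycle_predictive(
    sim, cycle: int, now: int,
    upper: Optional[float] = None, lower: Optional[float] = None,
    forecaster: Optional[ForecastEngine] = None,
) -> list[MovementOrder]:
    """One-shot functional form of :class:`ProactiveController`."""
    return ProactiveController(upper, lower, forecaster).orders(sim, cycle, now)
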