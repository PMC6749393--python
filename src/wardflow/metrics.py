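"""Evaluation metrics over simulation logs.

Three metrics compare scenarios:

* **Maximum waiting time for care** -- per hour, the largest realized wait
  (service start minus queue entry) across all rooms; summarized by the
  weekly average of the hourly maxima (over hours in which care started) and
  the weekly maximum.
* **Human resources cost** -- the time average of the on-shift headcount
  plus 1.5 times the overtime headcount (staff allocated, or in allocation
  transit, outside their regular hours); overtime is paid at least 50% above
  a normal hour.
* **Elastic number of human resources used** -- the hourly mean of
  professionals present in rooms (in-transit staff are not in care);
  summarized by weekly average and weekly maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import TICKS_PER_HOUR, SimulationLog


def cost(ti: int, tf: int, staffing_log) -> float:
    """Hourly human-resources cost averaged over the ticks ``[ti, tf)``.

    ``staffing_log`` is a pair ``(hr, allocated_hr)`` of per-tick sequences:
    the on-shift headcount and the overtime (allocated or in allocation
    transit) headcount.  See :func:`cost_of_log` for the whole-run form.
    """
    if not tf > ti:
        raise ValueError("need tf > ti")
    hr, allocated = staffing_log
    hr = np.asarray(hr, dtype=float)[ti:tf]
    allocated = np.asarray(allocated, dtype=float)[ti:tf]
    return float(np.mean(hr + 1.5 * allocated))


def cost_of_log(log: SimulationLog) -> float:
    """Whole-run human-resources cost of a simulation log."""
    ticks = log.n_hours * TICKS_PER_HOUR
    total = log.hourly_onshift_sum.sum() + 1.5 * log.hourly_overtime_sum.sum()
    return float(total / ticks)


def hourly_cost(log: SimulationLog) -> np.ndarray:
    return (
        log.hourly_onshift_sum + 1.5 * log.hourly_overtime_sum
    ) / TICKS_PER_HOUR


@dataclass(frozen=True)
class MaxWaitStats:
    hourly: np.ndarray          # per-hour maximum realized wait, minutes
    data_hours: np.ndarray      # hours in which at least one care started
    weekly_average: float       # mean of hourly maxima over data hours
    weekly_max: float
    spread: float               # sd of hourly maxima over data hours


def max_wait_stats(log: SimulationLog) -> MaxWaitStats:
    """Hourly maximum realized waits and their weekly summary.

    Hours in which no care started contribute a recorded zero to the hourly
    series but are excluded from the weekly average, which otherwise would
    be diluted by closed-night hours with no patients.
    """
    hourly = log.hourly_max_wait
    mask = log.hourly_wait_count > 0
    if mask.any():
        avg = float(hourly[mask].mean())
        spread = float(hourly[mask].std(ddof=0))
        top = float(hourly.max())
    else:
        avg = spread = top = 0.0
    return MaxWaitStats(
        hourly=hourly, data_hours=mask,
        weekly_average=avg, weekly_max=top, spread=spread,
    )


@dataclass(frozen=True)
class ElasticHRStats:
    hourly_mean: np.ndarray
    weekly_average: float
    weekly_max: float


def elastic_hr_stats(log: SimulationLog) -> ElasticHRStats:
    """Hourly mean of professionals actively staffing rooms."""
    hourly = log.hourly_active_sum / TICKS_PER_HOUR
    return ElasticHRStats(
        hourly_mean=hourly,
        weekly_average=float(hourly.mean()) if len(hourly) else 0.0,
        weekly_max=float(hourly.max()) if len(hourly) else 0.0,
    )


@dataclass(frozen=True)
class ScenarioSummary:
    """One row of the scenario-comparison table."""

    workload: str
    scenario: str
    upper: Optional[float]
    lower: Optional[float]
    max_wait_average: float
    max_wait_upper: float
    max_wait_spread: float
    cost: float
    elastic_hr_average: float
    elastic_hr_max: float
    seed: int
    config_hash: str


def summarize(
    log: SimulationLog,
    workload: str,
    scenario: str,
    upper: Optional[float] = None,
    lower: Optional[float] = None,
) -> ScenarioSummary:
    waits = max_wait_stats(log)
    hr = elastic_hr_stats(log)
    return ScenarioSummary(
        workload=workload,
        scenario=scenario,
        upper=upper,
        lower=lower,
        max_wait_average=waits.weekly_average,
        max_wait_upper=waits.weekly_max,
        max_wait_spread=waits.spread,
        cost=cost_of_log(log),
        elastic_hr_average=hr.weekly_average,
        elastic_hr_max=hr.weekly_max,
        seed=log.seed,
        config_hash=log.config_hash,
    )


def summary_frame(rows: Sequence[ScenarioSummary]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in rows])
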