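"""Synthetic patient-arrival workloads.

Four daily demand shapes drive the simulator: *constant*, *ascending*,
*descending* and *wave*.  A profile yields a fractional arrival rate
(patients per simulation tick) at every instant of one day of care; the
engine tiles the day across the simulated horizon.  Because a fraction of a
patient cannot enter a hospital, fractional rates are converted to integer
admissions by a load-accumulation rule: the fractional remainder of each tick
is carried into the next one, so that offered load is conserved exactly.

Amplitudes are calibration parameters rather than fixed constants: the
:func:`calibrate_wave_amplitude` helper searches the amplitude at which a
static-staffing week reaches a stated average of hourly maximum waiting
times, which anchors the simulated load to a published operating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

SHAPES = ("constant", "ascending", "descending", "wave")


@dataclass(frozen=True)
class WorkloadProfile:
    """Daily arrival-rate profile.

    Parameters
    ----------
    shape
        One of ``constant``, ``ascending``, ``descending``, ``wave``.
    amplitude
        Peak arrival rate, in patients per tick.
    duration
        Length of the profile domain in minutes (one day of care).
    period
        Wave period in minutes (wave shape only); defaults to ``duration``.
    """

    shape: str
    amplitude: float
    duration: float = 1440.0
    period: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown workload shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.shape == "wave":
            period = self.period if self.period is not None else self.duration
            if period <= 0:
                raise ValueError("wave period must be > 0")

    def with_amplitude(self, amplitude: float) -> "WorkloadProfile":
        return replace(self, amplitude=amplitude)


def rate_at(profile: WorkloadProfile, t: float) -> float:
    """Fractional patients offered at minute ``t`` of the profile's day.

    The wave starts at mid-amplitude rising, oscillating in
    ``[0, amplitude]``: ``A/2 * (1 + sin(2*pi*t/period))``.
    """
    if not 0 <= t <= profile.duration:
        raise ValueError(
            f"t={t} outside workload domain [0, {profile.duration}]"
        )
    a = profile.amplitude
    if profile.shape == "constant":
        return a
    if profile.shape == "ascending":
        return a * t / profile.duration
    if profile.shape == "descending":
        return a * (1.0 - t / profile.duration)
    period = profile.period if profile.period is not None else profile.duration
    return 0.5 * a * (1.0 + math.sin(2.0 * math.pi * t / period))


@dataclass
class ArrivalAccumulator:
    """Carries fractional patients between ticks so no load is lost."""

    carry: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.carry < 1.0:
            raise ValueError("carry must lie in [0, 1)")


def integer_arrivals(
    rate: float, acc: ArrivalAccumulator
) -> tuple[int, ArrivalAccumulator]:
    """Convert a fractional rate into whole admissions.

    The offered ``rate`` is added to the accumulated carry; the integer part
    enters the hospital and the remainder is carried forward.  Example: two
    consecutive ticks of 0.6 patient admit nobody, then one patient, leaving
    a carry of 0.2.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    total = acc.carry + rate
    count = int(math.floor(total))
    return count, ArrivalAccumulator(total - count)


def calibrate_wave_amplitude(
    target_avg_max_wait: float,
    *,
    scenario=None,
    seed: int = 0,
    days: int = 7,
    rel_tol: float = 0.05,
    initial_amplitude: float = 0.02,
    max_iter: int = 24,
) -> float:
    """Search the wave amplitude at which a static-staffing (no controller)
    run reaches ``target_avg_max_wait`` minutes of average hourly maximum
    waiting time.

    The average maximum waiting time of the uncontrolled hospital increases
    monotonically with the offered load (up to simulation noise), so a
    bracketing bisection on the amplitude suffices.  Returns the calibrated
    amplitude (patients per tick at the wave peak).
    """
    from .engine import run_scenario  # local import: avoid circular dependency
    from .scenario import polyclinic

    if scenario is None:
        scenario = polyclinic()

    def measure(amplitude: float) -> float:
        from .metrics import max_wait_stats

        profile = WorkloadProfile("wave", amplitude)
        log = run_scenario(
            scenario, profile, controller_mode="none", seed=seed,
            duration_minutes=days * 1440.0,
        )
        return max_wait_stats(log).weekly_average

    lo, hi = 0.0, initial_amplitude
    wait_hi = measure(hi)
    while wait_hi < target_avg_max_wait:
        lo, hi = hi, hi * 2.0
        wait_hi = measure(hi)
        if hi > 1e3:  # pragma: no cover - defensive
            raise RuntimeError("calibration failed to bracket the target")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        wait_mid = measure(mid)
        if abs(wait_mid - target_avg_max_wait) <= rel_tol * target_avg_max_wait:
            return mid
        if wait_mid < target_avg_max_wait:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
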