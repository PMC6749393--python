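"""Care-time mathematics and demand forecasting.

The elasticity controllers reason about a room's load through a small set of
pure quantities:

* ``ACT`` -- average care time: mean of the completed care durations in a
  window (the *care vector*).
* ``ANA`` -- average number of attendants allocated to the room over a window.
* ``ENP`` -- estimated number of patients: those already waiting plus the
  incoming ones over the window.
* ``ECT = ACT * ENP`` -- estimated time to care for everyone in the queue
  with a single attendant.
* ``HRES = ECT / ANA`` -- the same queue served by attendants in parallel;
  the estimated wait of a newly arriving patient.  Doubling attendants halves
  it.
* ``PHRES = (ACT' * ENP') / a`` -- the proactive counterpart, where primed
  quantities are forecasts over a future window and ``a`` is a hypothetical
  attendant count.

Forecasts of the per-cycle average-care-time and incoming-patients series use
an ARIMA(1,1,1) model fitted on a trailing window, with a trailing-mean
fallback whenever the series is too short or degenerate for a model fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

INFINITE_WAIT = math.inf

#: minimum series length (monitoring cycles) before an ARIMA fit is attempted
MIN_FIT_WINDOW = 24
#: trailing window of monitoring cycles used for model fitting (24 h at 10 min)
TRAIN_WINDOW = 144
#: cycles between full re-optimizations of the ARIMA parameters
REFIT_EVERY = 6
#: cycles of trailing data averaged by the fallback forecaster
FALLBACK_WINDOW = 12


class EmptyCareVector(ValueError):
    """The care vector holds no completed care; ACT is undefined."""


# ---------------------------------------------------------------------------
# Measured-state quantities
# ---------------------------------------------------------------------------

def act(care_vector: Sequence[float]) -> float:
    """Average care time: arithmetic mean of completed care durations."""
    if len(care_vector) == 0:
        raise EmptyCareVector("cannot average an empty care vector")
    return float(np.mean(care_vector))


def ana(na_series: Sequence[float], ti: int = 0, tf: int | None = None) -> float:
    """Average number of attendants over the ticks ``[ti, tf)``."""
    if tf is None:
        tf = len(na_series)
    if not tf > ti:
        raise ValueError("need tf > ti")
    return float(np.mean(np.asarray(na_series, dtype=float)[ti:tf]))


def enp(
    nwp_at_ti: float,
    nip_series: Sequence[float],
    ti: int | None = None,
    tf: int | None = None,
) -> float:
    """Estimated number of patients needing care over a window.

    Patients already waiting at the window start plus the incoming patients
    at the interior instants ``ti+1 .. tf-1``.  Without explicit bounds the
    whole incoming series is summed.
    """
    series = np.asarray(nip_series, dtype=float)
    if ti is None and tf is None:
        incoming = series
    else:
        if ti is None or tf is None or not tf > ti:
            raise ValueError("need both bounds with tf > ti")
        incoming = series[ti + 1 : tf]
    return float(nwp_at_ti + incoming.sum())


def ect(act_value: float, enp_value: float) -> float:
    """Estimated care time of the whole queue with one attendant."""
    if act_value < 0 or enp_value < 0:
        raise ValueError("ACT and ENP must be >= 0")
    return act_value * enp_value


def hres(ect_value: float, ana_value: float) -> float:
    """Estimated wait with ``ana_value`` attendants serving in parallel."""
    if ana_value < 0:
        raise ValueError("attendant count must be >= 0")
    if ana_value == 0:
        return INFINITE_WAIT
    return ect_value / ana_value


def phres(act_prime: float, enp_prime: float, a: float) -> float:
    """Forecast-based wait with ``a`` attendants serving in parallel."""
    return hres(ect(act_prime, enp_prime), a)


# ---------------------------------------------------------------------------
# Time-series bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class RoomSeries:
    """Per-cycle history of one room (zero-filled, no gaps)."""

    act: list[float] = field(default_factory=list)
    nip: list[float] = field(default_factory=list)
    nwp: list[float] = field(default_factory=list)
    na_mean: list[float] = field(default_factory=list)
    wait_est: list[float] = field(default_factory=list)

    def append_cycle(
        self, act_value: float, nip_value: float, nwp_value: float,
        na_value: float, wait_value: float,
    ) -> None:
        self.act.append(act_value)
        self.nip.append(nip_value)
        self.nwp.append(nwp_value)
        self.na_mean.append(na_value)
        self.wait_est.append(wait_value)

    def __len__(self) -> int:
        return len(self.act)


class TimeSeriesStore:
    """Per-room monitoring-cycle series feeding controllers and forecasts."""

    def __init__(self, room_names: Sequence[str]):
        self.rooms: dict[str, RoomSeries] = {name: RoomSeries() for name in room_names}

    def __getitem__(self, room: str) -> RoomSeries:
        return self.rooms[room]

    def to_frame(self):
        import pandas as pd

        records = []
        for room, series in self.rooms.items():
            for cycle in range(len(series)):
                records.append(
                    {
                        "cycle": cycle,
                        "room": room,
                        "act": series.act[cycle],
                        "nip": series.nip[cycle],
                        "nwp": series.nwp[cycle],
                        "na_mean": series.na_mean[cycle],
                        "wait_est": series.wait_est[cycle],
                    }
                )
        return pd.DataFrame.from_records(
            records, columns=["cycle", "room", "act", "nip", "nwp", "na_mean",
                              "wait_est"]
        )


# ---------------------------------------------------------------------------
# Forecasting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Forecast:
    """Nonnegative predictions over a horizon of monitoring cycles."""

    values: tuple[float, ...]
    fallback: bool
    order: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):  # pragma: no cover - clipped upstream
            raise ValueError("forecast values must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else 0.0

    @property
    def total(self) -> float:
        return float(np.sum(self.values))


def _fallback_forecast(series: np.ndarray, horizon: int) -> Forecast:
    window = series[-FALLBACK_WINDOW:] if len(series) else np.zeros(1)
    level = float(np.mean(window)) if len(window) else 0.0
    return Forecast(values=(max(level, 0.0),) * horizon, fallback=True)


def forecast(
    series: Sequence[float],
    horizon: int,
    order: tuple[int, int, int] = (1, 1, 1),
) -> Forecast:
    """Forecast ``horizon`` future cycles of a per-cycle series.

    Fits an ARIMA model of the given order on the trailing training window.
    Falls back to the trailing-window mean (flagged on the result) when the
    series is shorter than the minimum window, degenerate (constant or all
    zero), or the fit fails.  Predictions are clipped at zero: neither care
    times nor patient counts can be negative.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    arr = np.asarray(series, dtype=float)
    if len(arr) < MIN_FIT_WINDOW or np.allclose(arr, arr[-1]):
        return _fallback_forecast(arr, horizon)
    train = arr[-TRAIN_WINDOW:]
    try:
        from statsmodels.tsa.arima.model import ARIMA

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(
                train, order=order,
                enforce_stationarity=False, enforce_invertibility=False,
            ).fit(method_kwargs={"maxiter": 50})
            pred = np.asarray(res.forecast(horizon), dtype=float)
    except Exception:
        return _fallback_forecast(arr, horizon)
    if not np.all(np.isfinite(pred)):
        return _fallback_forecast(arr, horizon)
    return Forecast(
        values=tuple(np.clip(pred, 0.0, None)), fallback=False, order=order
    )


class ForecastEngine:
    """Incremental per-series ARIMA forecaster for simulation use.

    Re-optimizing ARIMA parameters at every monitoring cycle would dominate
    the simulation cost, so the engine re-fits each series every
    ``refit_every`` cycles and, in between, folds new observations into the
    fitted state-space model (a Kalman-filter update, no re-optimization).
    """

    def __init__(
        self,
        order: tuple[int, int, int] = (1, 1, 1),
        refit_every: int = REFIT_EVERY,
    ):
        self.order = order
        self.refit_every = refit_every
        self._results: dict[str, object] = {}
        self._seen: dict[str, int] = {}
        self._last_fit_at: dict[str, int] = {}

    def predict(self, key: str, series: Sequence[float], horizon: int) -> Forecast:
        arr = np.asarray(series, dtype=float)
        n = len(arr)
        if n < MIN_FIT_WINDOW or np.allclose(arr, arr[-1]):
            return _fallback_forecast(arr, horizon)

        res = self._results.get(key)
        needs_refit = (
            res is None or n - self._last_fit_at.get(key, -10**9) >= self.refit_every
        )
        try:
            from statsmodels.tsa.arima.model import ARIMA

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if needs_refit:
                    train = arr[-TRAIN_WINDOW:]
                    res = ARIMA(
                        train, order=self.order,
                        enforce_stationarity=False, enforce_invertibility=False,
                    ).fit(method_kwargs={"maxiter": 50})
                    self._results[key] = res
                    self._seen[key] = n
                    self._last_fit_at[key] = n
                else:
                    new = arr[self._seen[key]:]
                    if len(new):
                        res = res.append(new, refit=False)
                        self._results[key] = res
                        self._seen[key] = n
                pred = np.asarray(res.forecast(horizon), dtype=float)
        except Exception:
            self._results.pop(key, None)
            return _fallback_forecast(arr, horizon)
        if not np.all(np.isfinite(pred)):
            return _fallback_forecast(arr, horizon)
        return Forecast(
            values=tuple(np.clip(pred, 0.0, None)), fallback=False, order=self.order
        )
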