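"""Static mixing-model inference for the two-source, one-tracer case.

Two estimators of the proportion of source a in the diet:

* ``smm_instant`` solves the two-endmember mixing line at each consumer
  sample time ("instantaneous" estimator).
* ``smm_integrated`` replaces each corrected source value by its trailing
  mean over a window of ``window_multiplier`` half-lives before solving the
  same line ("integrated" estimator); estimates are only emitted once a
  full window fits inside the record.

Estimates outside [0, 1] (consumer outside the mixing polygon) are returned
unclipped with ``in_polygon=False`` so downstream bias statistics see the
raw differences; clipping is an explicit opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidInputError,
    UndefinedMixtureError,
    WindowTooLongError,
)
from .forcing import DietSchedule, SourcePool, TimeSeries, TurnoverSchedule

__all__ = [
    "DietEstimate",
    "smm_instant",
    "smm_integrated",
    "reference_diet_windowed",
]

POLYGON_TOL = 1e-12
#: denominator guard for coincident corrected sources
_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class DietEstimate:
    """Estimated proportion of source a over time, with method metadata.

    ``window`` holds the per-time integration window length in days
    (``None`` for instantaneous estimates).
    """

    method: str
    times: np.ndarray
    p_hat: np.ndarray
    in_polygon: np.ndarray
    window: np.ndarray | None = None
    window_multiplier: float | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        p_hat = np.asarray(self.p_hat, dtype=float)
        if times.size != p_hat.size:
            raise InvalidInputError("times and p_hat must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        in_poly = (p_hat >= -POLYGON_TOL) & (p_hat <= 1 + POLYGON_TOL)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "p_hat", p_hat)
        object.__setattr__(self, "in_polygon", in_poly)
        object.__setattr__(
            self,
            "window",
            None if self.window is None else np.asarray(self.window, float),
        )


def _two_endmember(delta_c, corrected_a, corrected_b, times):
    denom = corrected_a - corrected_b
    bad = np.abs(denom) < _DEGENERATE_TOL
    if np.any(bad):
        t_bad = float(np.asarray(times)[np.argmax(bad)])
        raise UndefinedMixtureError(t_bad)
    return (delta_c - corrected_b) / denom


def smm_instant(consumer: TimeSeries, pool: SourcePool) -> DietEstimate:
    """Instantaneous two-endmember estimate at each consumer sample time."""
    if pool.n_sources != 2:
        raise InvalidInputError("instantaneous inference needs exactly 2 sources")
    t = consumer.times
    p_hat = _two_endmember(
        consumer.values, pool.corrected(0, t), pool.corrected(1, t), t
    )
    return DietEstimate("SMM_t", t, p_hat, np.empty(0))


def _window_lengths(turnover: TurnoverSchedule, times, multiplier: float):
    return multiplier * math.log(2) / np.asarray(turnover.rate(times), float)


def _trailing_mean(series_fn, t: float, width: float, step: float) -> float:
    """Mean of ``series_fn`` over samples t, t-step, ..., back through width."""
    n_back = int(math.floor(width / step + 1e-9))
    sample_times = t - step * np.arange(n_back + 1)
    return float(np.mean(series_fn(sample_times)))


def smm_integrated(
    consumer: TimeSeries,
    pool: SourcePool,
    turnover: TurnoverSchedule,
    window_multiplier: float = 2.0,
    sample_step: float = 1.0,
    clip: bool = False,
) -> DietEstimate:
    """Window-integrated two-endmember estimate.

    The window length at time ``t`` is ``window_multiplier * ln(2) /
    lambda(t)``; each corrected source enters as its trailing mean sampled
    every ``sample_step`` days over ``[t - window, t]`` (both endpoints
    included).  Estimates are emitted only where the full window fits after
    the start of the consumer record.
    """
    if pool.n_sources != 2:
        raise InvalidInputError("integrated inference needs exactly 2 sources")
    if window_multiplier < 0:
        raise InvalidInputError("window_multiplier must be >= 0")
    t = consumer.times
    t0, t_end = consumer.span
    widths = _window_lengths(turnover, t, window_multiplier)
    emit = t - t0 >= widths - 1e-9
    if not np.any(emit):
        raise WindowTooLongError(
            "integration window exceeds the sampled span everywhere"
        )
    times = t[emit]
    widths = widths[emit]
    p_hat = np.empty(times.size)
    for j, (tj, wj) in enumerate(zip(times, widths)):
        mean_a = _trailing_mean(lambda s: pool.corrected(0, s), tj, wj, sample_step)
        mean_b = _trailing_mean(lambda s: pool.corrected(1, s), tj, wj, sample_step)
        p_hat[j] = _two_endmember(consumer.at(tj), mean_a, mean_b, tj)
    if clip:
        p_hat = np.clip(p_hat, 0.0, 1.0)
    return DietEstimate(
        "SMM_Dt",
        times,
        p_hat,
        np.empty(0),
        window=widths,
        window_multiplier=window_multiplier,
    )


def reference_diet_windowed(
    schedule: DietSchedule,
    turnover: TurnoverSchedule,
    window_multiplier: float = 2.0,
    times: np.ndarray | None = None,
    sample_step: float = 1.0,
) -> DietEstimate:
    """Forced proportion of source a averaged over the same trailing windows.

    This is the comparison reference for the integrated estimator: the
    known schedule is averaged over exactly the windows ``smm_integrated``
    uses, on the same inclusive sample grid.
    """
    if times is None:
        times = schedule.times
    times = np.asarray(times, dtype=float)
    t0 = float(times[0])
    widths = _window_lengths(turnover, times, window_multiplier)
    emit = times - t0 >= widths - 1e-9
    if not np.any(emit):
        raise WindowTooLongError(
            "integration window exceeds the sampled span everywhere"
        )
    out_t = times[emit]
    out_w = widths[emit]
    p_ref = np.empty(out_t.size)
    for j, (tj, wj) in enumerate(zip(out_t, out_w)):
        p_ref[j] = _trailing_mean(
            lambda s: schedule.proportion(0, s), tj, wj, sample_step
        )
    return DietEstimate(
        "reference",
        out_t,
        p_ref,
        np.empty(0),
        window=out_w,
        window_multiplier=window_multiplier,
    )
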