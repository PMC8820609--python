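"""Time-varying forcing inputs: source trajectories, diet schedules, turnover.

Everything a consumer-isotope simulation is driven by lives here: sampled
``TimeSeries`` trajectories with continuous-time (linear, clamped)
evaluation, pools of discrimination-corrected sources, binary diet-switch
schedules generated from a switch frequency, and turnover-rate schedules
(constant, exponentially decaying, or tabulated per period).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientTrajectoriesError, InvalidInputError

__all__ = [
    "TimeSeries",
    "BrownianSpec",
    "ConstantSourcesSpec",
    "SourcePool",
    "DietSchedule",
    "TurnoverSchedule",
    "constant_sources",
    "simulate_brownian_sources",
    "diet_switch_schedule",
    "switch_times",
    "make_turnover",
    "evaluate_forcing",
]


@dataclass(frozen=True)
class TimeSeries:
    """A sampled trajectory of per-mil values on a day grid.

    Parameters
    ----------
    times
        Sample times in days; non-negative, strictly increasing, length >= 2.
    values
        Per-mil values, finite, same length as ``times``.
    label
        Free-text label used in output tables.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1:
            raise InvalidInputError("times and values must be 1-D")
        if times.size != values.size or times.size < 2:
            raise InvalidInputError(
                "times and values must have equal length >= 2"
            )
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise InvalidInputError("times must be finite and non-negative")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def covers(self, t0: float, t1: float, tol: float = 1e-9) -> bool:
        return self.times[0] <= t0 + tol and self.times[-1] >= t1 - tol

    def at(self, t):
        """Linear interpolation with endpoint-clamped extrapolation."""
        return np.interp(t, self.times, self.values)


def evaluate_forcing(series: TimeSeries, t):
    """Evaluate a sampled forcing series at arbitrary times.

    Linear interpolation between bracketing samples; outside the sampled
    range the nearest endpoint value is returned (clamped), so adaptive ODE
    solvers probing slightly past the horizon never fail.
    """
    return series.at(t)


@dataclass(frozen=True)
class ConstantSourcesSpec:
    """Serializable description of a flat-source pool."""

    values: tuple[float, ...]
    tdfs: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(self, "tdfs", tuple(float(v) for v in self.tdfs))
        if len(self.values) == 0:
            raise InvalidInputError("at least one source value is required")
        if len(self.values) != len(self.tdfs):
            raise InvalidInputError("one discrimination factor per source value")


@dataclass(frozen=True)
class BrownianSpec:
    """Parameters of the Brownian source-pair generator.

    ``n_candidates`` independent pairs are simulated; pairs whose
    trajectories ever come within ``min_separation`` of each other are
    discarded and ``n_keep`` survivors are drawn uniformly at random.
    """

    initial_values: tuple[float, float] = (0.0, 10.0)
    step_variance: float = 0.2
    n_candidates: int = 150
    n_keep: int = 100
    min_separation: float = 2.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "initial_values", tuple(float(v) for v in self.initial_values)
        )
        if self.step_variance < 0:
            raise InvalidInputError("step_variance must be >= 0")
        if self.min_separation < 0:
            raise InvalidInputError("min_separation must be >= 0")
        if self.n_keep > self.n_candidates:
            raise InvalidInputError("n_keep must not exceed n_candidates")
        if self.n_keep < 1:
            raise InvalidInputError("n_keep must be >= 1")


@dataclass(frozen=True)
class SourcePool:
    """Source trajectories, each paired with a constant discrimination factor."""

    sources: tuple[tuple[TimeSeries, float], ...]

    def __post_init__(self):
        sources = tuple((ts, float(tdf)) for ts, tdf in self.sources)
        if len(sources) == 0:
            raise InvalidInputError("a source pool cannot be empty")
        object.__setattr__(self, "sources", sources)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def trajectories(self) -> tuple[TimeSeries, ...]:
        return tuple(ts for ts, _ in self.sources)

    @property
    def tdfs(self) -> tuple[float, ...]:
        return tuple(tdf for _, tdf in self.sources)

    def corrected(self, i: int, t):
        """Discrimination-corrected value of source ``i`` at time(s) ``t``."""
        ts, tdf = self.sources[i]
        return ts.at(t) + tdf

    def covers(self, t0: float, t1: float) -> bool:
        return all(ts.covers(t0, t1) for ts, _ in self.sources)


SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class DietSchedule:
    """Per-source diet proportions over time.

    When ``switch_frequency`` is set the schedule was produced by the binary
    switch generator and proportions are evaluated exactly from the sign of
    ``sin(pi * omega * t)`` rather than by interpolating the samples; the
    stored sample series then only serve as a gridded view.  ``interp``
    selects linear or previous-value (step) interpolation for sampled
    schedules.
    """

    proportions: tuple[TimeSeries, ...]
    switch_frequency: float | None = None
    interp: str = "linear"

    def __post_init__(self):
        props = tuple(self.proportions)
        if len(props) == 0:
            raise InvalidInputError("a diet schedule needs at least one source")
        object.__setattr__(self, "proportions", props)
        if self.interp not in ("linear", "previous"):
            raise InvalidInputError("interp must be 'linear' or 'previous'")
        base = props[0].times
        stack = []
        for series in props:
            if series.times.shape != base.shape or np.any(series.times != base):
                raise InvalidInputError(
                    "all proportion series must share one time grid"
                )
            if np.any(series.values < -SIMPLEX_TOL) or np.any(
                series.values > 1 + SIMPLEX_TOL
            ):
                raise InvalidInputError("proportions must lie in [0, 1]")
            stack.append(series.values)
        total = np.sum(stack, axis=0)
        if np.any(np.abs(total - 1.0) > SIMPLEX_TOL):
            raise InvalidInputError(
                "proportions must sum to 1 at every shared time point"
            )

    @property
    def n_sources(self) -> int:
        return len(self.proportions)

    @property
    def times(self) -> np.ndarray:
        return self.proportions[0].times

    def covers(self, t0: float, t1: float) -> bool:
        return all(p.covers(t0, t1) for p in self.proportions)

    def proportion(self, i: int, t):
        """Proportion of source ``i`` at time(s) ``t``."""
        if self.switch_frequency is not None and self.n_sources == 2:
            pa = _binary_switch(self.switch_frequency, t)
            return pa if i == 0 else 1.0 - pa
        series = self.proportions[i]
        if self.interp == "previous":
            idx = np.searchsorted(series.times, t, side="right") - 1
            idx = np.clip(idx, 0, series.times.size - 1)
            return series.values[idx]
        return series.at(t)

    def breakpoints(self, horizon: float) -> np.ndarray:
        """Times in (0, horizon) where the schedule may jump."""
        if self.switch_frequency is not None:
            return switch_times(self.switch_frequency, horizon)
        if self.interp == "previous":
            times = self.times
            return times[(times > 0) & (times < horizon)]
        return np.empty(0)


#: sin(pi*k) evaluates to ~1e-16 rather than 0 in floats; values this close
#: to zero are treated as the tie-break (else-branch) case
_SIN_TOL = 1e-12


def _binary_switch(omega: float, t):
    """Exact binary proportion of source a: 1 where sin(pi*omega*t) > 0.

    At zeros of the sine (including t = 0 and omega = 0) the else-branch
    applies and source a gets proportion 0.
    """
    s = np.sin(np.pi * omega * np.asarray(t, dtype=float))
    return np.where(s > _SIN_TOL, 1.0, 0.0)


def switch_times(omega: float, horizon: float) -> np.ndarray:
    """Diet-switch times k/omega inside (0, horizon]."""
    if omega <= 0:
        return np.empty(0)
    n = int(math.floor(omega * horizon + 1e-12))
    return np.arange(1, n + 1) / omega


def constant_sources(
    values: Sequence[float],
    tdfs: Sequence[float],
    horizon: float,
    step: float = 1.0,
) -> SourcePool:
    """Build a pool of flat source trajectories over ``[0, horizon]``.

    Equivalent to the Brownian generator with zero step variance.
    """
    values = tuple(float(v) for v in values)
    tdfs = tuple(float(v) for v in tdfs)
    if len(values) == 0:
        raise InvalidInputError("at least one source value is required")
    if len(values) != len(tdfs):
        raise InvalidInputError("one discrimination factor per source value")
    if horizon <= 0:
        raise InvalidInputError("horizon must be positive")
    grid = _day_grid(horizon, step)
    sources = tuple(
        (
            TimeSeries(grid, np.full(grid.size, v), label=f"source_{chr(97 + i)}"),
            tdf,
        )
        for i, (v, tdf) in enumerate(zip(values, tdfs))
    )
    return SourcePool(sources)


def simulate_brownian_sources(
    spec: BrownianSpec,
    horizon: float,
    tdfs: Sequence[float] = (1.0, 1.0),
) -> list[SourcePool]:
    """Simulate filtered Brownian source pairs on a daily grid.

    Each candidate pair follows independent random walks
    ``delta(t + 1) = delta(t) + V(t)`` with ``V ~ Normal(0, step_variance)``.
    Pairs whose trajectories ever come within ``min_separation`` per-mil of
    each other are discarded; ``n_keep`` survivors are then drawn uniformly
    without replacement, reproducibly under ``spec.seed``.

    Raises
    ------
    InsufficientTrajectoriesError
        If fewer than ``n_keep`` pairs survive the filter.  The survivor
        count is reported; the filter is never silently relaxed.
    """
    if horizon < 1:
        raise InvalidInputError("horizon must be at least 1 day")
    tdfs = tuple(float(v) for v in tdfs)
    if len(tdfs) != 2:
        raise InvalidInputError("exactly two discrimination factors expected")
    rng = np.random.default_rng(spec.seed)
    grid = np.arange(0.0, math.floor(horizon) + 1.0)
    n_steps = grid.size - 1
    sigma = math.sqrt(spec.step_variance)
    increments = rng.normal(
        0.0, sigma, size=(spec.n_candidates, 2, n_steps)
    ) if sigma > 0 else np.zeros((spec.n_candidates, 2, n_steps))
    start = np.asarray(spec.initial_values, dtype=float).reshape(1, 2, 1)
    paths = np.concatenate(
        [np.broadcast_to(start, (spec.n_candidates, 2, 1)),
         start + np.cumsum(increments, axis=2)],
        axis=2,
    )
    separation = np.abs(paths[:, 0, :] - paths[:, 1, :])
    survivors = np.flatnonzero(np.all(separation >= spec.min_separation, axis=1))
    if survivors.size < spec.n_keep:
        raise InsufficientTrajectoriesError(int(survivors.size), spec.n_keep)
    chosen = rng.choice(survivors, size=spec.n_keep, replace=False)
    pools = []
    for j, idx in enumerate(chosen):
        pair = tuple(
            (
                TimeSeries(grid, paths[idx, k, :], label=f"source_{'ab'[k]}_{j}"),
                tdfs[k],
            )
            for k in range(2)
        )
        pools.append(SourcePool(pair))
    return pools


def diet_switch_schedule(
    omega: float, horizon: float, step: float = 1.0
) -> DietSchedule:
    """Binary two-source diet schedule driven by a switch frequency.

    Source a receives the full diet wherever ``sin(pi * omega * t) > 0``
    and nothing elsewhere; source b takes the complement.  Switches occur
    at ``t = k / omega``.  ``omega = 0`` is legal and pins the diet to
    source b.
    """
    if omega < 0:
        raise InvalidInputError("omega must be >= 0")
    if horizon <= 0:
        raise InvalidInputError("horizon must be positive")
    grid = _day_grid(horizon, step)
    pa = _binary_switch(omega, grid)
    series_a = TimeSeries(grid, pa, label="p_source_a")
    series_b = TimeSeries(grid, 1.0 - pa, label="p_source_b")
    return DietSchedule(
        (series_a, series_b), switch_frequency=float(omega), interp="previous"
    )


@dataclass(frozen=True)
class TurnoverSchedule:
    """Turnover rate lambda(t) > 0 with its derived half-life.

    ``mode`` is one of ``constant``, ``exponential`` (``lambda0 *
    exp(-alpha * t)``) or ``tabulated`` (piecewise-constant per contiguous
    period, clamped to the nearest period outside the table).
    """

    mode: str
    lambda0: float | None = None
    alpha: float | None = None
    table: tuple[tuple[float, float, float], ...] | None = None

    def rate(self, t):
        """lambda(t) in 1/day."""
        t = np.asarray(t, dtype=float)
        if self.mode == "constant":
            out = np.full(t.shape, self.lambda0)
        elif self.mode == "exponential":
            out = self.lambda0 * np.exp(-self.alpha * t)
        else:
            starts = np.array([row[0] for row in self.table])
            lams = np.array([row[2] for row in self.table])
            idx = np.clip(
                np.searchsorted(starts, t, side="right") - 1, 0, lams.size - 1
            )
            out = lams[idx]
        return out if out.shape else float(out)

    def half_life(self, t):
        """ln(2) / lambda(t), in days."""
        return math.log(2) / self.rate(t)

    def breakpoints(self) -> np.ndarray:
        if self.mode == "tabulated":
            edges = [row[0] for row in self.table] + [self.table[-1][1]]
            return np.asarray(edges, dtype=float)
        return np.empty(0)

    @property
    def span(self) -> tuple[float, float] | None:
        if self.mode == "tabulated":
            return float(self.table[0][0]), float(self.table[-1][1])
        return None


def make_turnover(
    mode: str,
    lambda0: float | None = None,
    alpha: float | None = None,
    table: Iterable[tuple[float, float, float]] | None = None,
) -> TurnoverSchedule:
    """Construct a turnover schedule, validating positivity.

    ``table`` rows are ``(start_d, end_d, lambda_per_d)`` and must be
    contiguous with strictly positive rates.
    """
    if mode == "constant":
        if lambda0 is None or lambda0 <= 0:
            raise InvalidInputError("constant mode needs lambda0 > 0")
        return TurnoverSchedule(mode="constant", lambda0=float(lambda0))
    if mode == "exponential":
        if lambda0 is None or lambda0 <= 0:
            raise InvalidInputError("exponential mode needs lambda0 > 0")
        if alpha is None or alpha < 0:
            raise InvalidInputError("exponential mode needs alpha >= 0")
        return TurnoverSchedule(
            mode="exponential", lambda0=float(lambda0), alpha=float(alpha)
        )
    if mode == "tabulated":
        rows = tuple(
            (float(s), float(e), float(lam)) for s, e, lam in (table or ())
        )
        if not rows:
            raise InvalidInputError("tabulated mode needs a non-empty table")
        for start, end, lam in rows:
            if end <= start:
                raise InvalidInputError("each period must have end > start")
            if lam <= 0:
                raise InvalidInputError("turnover rates must be positive")
        for (s0, e0, _), (s1, _, _) in zip(rows, rows[1:]):
            if abs(e0 - s1) > 1e-9:
                raise InvalidInputError("periods must be contiguous")
        return TurnoverSchedule(mode="tabulated", table=rows)
    raise InvalidInputError(f"unknown turnover mode {mode!r}")


def _day_grid(horizon: float, step: float) -> np.ndarray:
    if step <= 0:
        raise InvalidInputError("step must be positive")
    n = int(round(horizon / step))
    grid = np.arange(n + 1) * step
    if grid[-1] < horizon - 1e-9:
        grid = np.append(grid, horizon)
    return grid
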