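"""Dynamic mixing model: forward simulation of a consumer's isotope value.

The consumer state obeys the first-order incorporation ODE

    d(delta_c)/dt = lambda(t) * (delta_d(t) - delta_c)

where ``delta_d(t)`` is the discrimination-corrected, proportion-weighted
mixture of the source trajectories.  The constant-rate, constant-diet case
has the closed form ``delta_inf + (delta_c0 - delta_inf) * exp(-lambda*t)``
which is exposed as an oracle alongside the numerical integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import CoverageError, InvalidInputError, InvalidTurnoverError
from .forcing import (
    BrownianSpec,
    ConstantSourcesSpec,
    DietSchedule,
    SourcePool,
    TimeSeries,
    TurnoverSchedule,
    constant_sources,
    diet_switch_schedule,
    simulate_brownian_sources,
)

__all__ = [
    "ScenarioConfig",
    "ConsumerTrajectory",
    "mix_diet",
    "analytic_constant_solution",
    "analytic_exponential_lambda_solution",
    "integrate_consumer",
    "simulate_consumer",
    "resolve_pool",
    "resolve_schedule",
]

#: solver tolerances; switch times are passed as segment boundaries so the
#: integrator restarts at each diet discontinuity instead of stepping across.
RTOL = 1e-8
ATOL = 1e-10


def mix_diet(pool: SourcePool, schedule: DietSchedule, t):
    """Corrected diet mixture: sum_i p_i(t) * (delta_s_i(t) + tdf_i)."""
    if pool.n_sources != schedule.n_sources:
        raise InvalidInputError(
            f"pool has {pool.n_sources} sources but schedule has "
            f"{schedule.n_sources}"
        )
    total = 0.0
    for i in range(pool.n_sources):
        total = total + schedule.proportion(i, t) * pool.corrected(i, t)
    return total


def analytic_constant_solution(
    delta_c0: float, delta_equilibrium: float, lam: float, t
):
    """Closed-form consumer value for constant rate and constant diet."""
    t = np.asarray(t, dtype=float)
    out = delta_equilibrium + (delta_c0 - delta_equilibrium) * np.exp(-lam * t)
    return out if out.shape else float(out)


def analytic_exponential_lambda_solution(
    delta_c0: float, delta_equilibrium: float, lambda0: float, alpha: float, t
):
    """Closed form for constant diet and exponentially decaying rate.

    Integrating the separable ODE with ``lambda(t) = lambda0*exp(-alpha*t)``
    gives an accumulated exposure ``(lambda0/alpha)*(1 - exp(-alpha*t))``.
    """
    t = np.asarray(t, dtype=float)
    if alpha == 0:
        exposure = lambda0 * t
    else:
        exposure = (lambda0 / alpha) * (1.0 - np.exp(-alpha * t))
    out = delta_equilibrium + (delta_c0 - delta_equilibrium) * np.exp(-exposure)
    return out if out.shape else float(out)


@dataclass
class ScenarioConfig:
    """A complete, serializable simulation scenario.

    ``sources`` may be a concrete :class:`SourcePool`, a
    :class:`ConstantSourcesSpec`, or a :class:`BrownianSpec` (realised at
    simulation time with ``seed``; ``source_tdfs`` then supplies the
    discrimination factors).  ``diet`` may be a concrete
    :class:`DietSchedule` or a bare switch frequency omega.
    ``initial_consumer=None`` starts the consumer at equilibrium with the
    initial corrected diet mixture.
    """

    sources: SourcePool | ConstantSourcesSpec | BrownianSpec
    turnover: TurnoverSchedule
    diet: DietSchedule | float = 0.002
    horizon: float = 500.0
    output_step: float = 1.0
    initial_consumer: float | None = None
    source_tdfs: tuple[float, ...] = (1.0, 1.0)
    seed: int = 0
    max_step: float = 1.0

    def __post_init__(self):
        if self.horizon <= 0:
            raise InvalidInputError("horizon must be positive")
        if self.output_step <= 0:
            raise InvalidInputError("output_step must be positive")


@dataclass(frozen=True)
class ConsumerTrajectory:
    """Simulated consumer series plus its moving equilibrium target."""

    consumer: TimeSeries
    diet_target: TimeSeries
    scenario: ScenarioConfig | None = None
    pool: SourcePool | None = None

    def __post_init__(self):
        if self.consumer.times.shape != self.diet_target.times.shape or np.any(
            self.consumer.times != self.diet_target.times
        ):
            raise InvalidInputError(
                "consumer and diet_target must share one time grid"
            )


def resolve_pool(config: ScenarioConfig) -> SourcePool:
    """Realise the configured sources as a concrete pool."""
    src = config.sources
    if isinstance(src, SourcePool):
        return src
    if isinstance(src, ConstantSourcesSpec):
        return constant_sources(src.values, src.tdfs, config.horizon)
    if isinstance(src, BrownianSpec):
        spec = replace(src, seed=config.seed)
        return simulate_brownian_sources(
            spec, config.horizon, tdfs=config.source_tdfs
        )[0]
    raise InvalidInputError(f"unsupported sources specification {type(src)!r}")


def resolve_schedule(config: ScenarioConfig) -> DietSchedule:
    if isinstance(config.diet, DietSchedule):
        return config.diet
    return diet_switch_schedule(float(config.diet), config.horizon)


def integrate_consumer(
    pool: SourcePool,
    schedule: DietSchedule,
    turnover: TurnoverSchedule,
    horizon: float,
    output_step: float = 1.0,
    delta_c0: float | None = None,
    max_step: float = 1.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> ConsumerTrajectory:
    """Numerically integrate the incorporation ODE over ``[0, horizon]``.

    Forcing is evaluated continuously (linear interpolation of sampled
    trajectories, exact evaluation of binary switch schedules); diet-switch
    times and turnover-table edges are used as integration breakpoints.
    Output is sampled on the regular ``output_step`` grid independently of
    the solver's internal steps.
    """
    if not pool.covers(0.0, horizon):
        raise CoverageError("source trajectories do not cover [0, horizon]")
    if schedule.switch_frequency is None and not schedule.covers(0.0, horizon):
        raise CoverageError("diet schedule does not cover [0, horizon]")
    tspan = turnover.span
    if tspan is not None and (tspan[0] > 1e-9 or tspan[1] < horizon - 1e-9):
        raise CoverageError("turnover table does not cover [0, horizon]")

    grid = np.round(np.arange(0.0, horizon + 0.5 * output_step, output_step), 12)
    if grid[-1] > horizon:
        grid = grid[:-1]
    if grid[-1] < horizon - 1e-9:
        grid = np.append(grid, horizon)
    lam_grid = np.asarray(turnover.rate(grid))
    if np.any(lam_grid <= 0) or not np.all(np.isfinite(lam_grid)):
        raise InvalidTurnoverError("lambda(t) must be positive and finite")

    if delta_c0 is None:
        delta_c0 = float(mix_diet(pool, schedule, 0.0))

    breaks = np.concatenate(
        [
            np.asarray([0.0, horizon]),
            schedule.breakpoints(horizon),
            turnover.breakpoints(),
        ]
    )
    breaks = np.unique(breaks[(breaks >= 0.0) & (breaks <= horizon)])

    out = np.empty(grid.size)
    out[0] = delta_c0
    y = delta_c0
    for left, right in zip(breaks[:-1], breaks[1:]):
        if right - left < 1e-12:
            continue
        # evaluate forcing just inside the open segment so binary switch
        # schedules take their interior value, not the boundary tie-break;
        # the 1e-6 d nudge keeps sin(pi*omega*t) clear of the zero tolerance
        lo = left + min(1e-6, 0.25 * (right - left))
        hi = right - min(1e-6, 0.25 * (right - left))

        def rhs(t, y, lo=lo, hi=hi):
            tt = min(max(t, lo), hi)
            return turnover.rate(tt) * (mix_diet(pool, schedule, tt) - y[0])

        sol = solve_ivp(
            rhs,
            (left, right),
            [y],
            method="RK45",
            dense_output=True,
            rtol=rtol,
            atol=atol,
            max_step=min(max_step, right - left),
        )
        if not sol.success:  # pragma: no cover - scipy failure path
            raise InvalidInputError(f"ODE solver failed: {sol.message}")
        y = float(sol.y[0, -1])
        sel = (grid > left + 1e-12) & (grid <= right + 1e-12)
        if np.any(sel):
            out[sel] = sol.sol(np.clip(grid[sel], left, right))[0]

    target = np.asarray(mix_diet(pool, schedule, grid), dtype=float)
    consumer = TimeSeries(grid, out, label="delta_c")
    diet_target = TimeSeries(grid, target, label="delta_target")
    return ConsumerTrajectory(consumer, diet_target, pool=pool)


def simulate_consumer(
    config: ScenarioConfig, pool: SourcePool | None = None
) -> ConsumerTrajectory:
    """Simulate a scenario, realising Brownian sources / omega as needed.

    ``pool`` overrides the configured sources (used by replicate sweeps).
    """
    pool = pool if pool is not None else resolve_pool(config)
    schedule = resolve_schedule(config)
    traj = integrate_consumer(
        pool,
        schedule,
        config.turnover,
        config.horizon,
        output_step=config.output_step,
        delta_c0=config.initial_consumer,
        max_step=config.max_step,
    )
    return ConsumerTrajectory(
        traj.consumer, traj.diet_target, scenario=config, pool=pool
    )


def first_passage_day(
    trajectory: ConsumerTrajectory,
    equilibrium: float,
    threshold: float,
) -> float | None:
    """First output day where |delta_c - equilibrium| < threshold, or None."""
    dev = np.abs(trajectory.consumer.values - equilibrium)
    hits = np.flatnonzero(dev < threshold)
    if hits.size == 0:
        return None
    return float(trajectory.consumer.times[hits[0]])
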