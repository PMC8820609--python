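"""Bias of static inference against the known forced diet, and sweeps.

The bias statistic is the summed absolute difference between the forced
and inferred proportions of source a, divided by the time span it covers:
the full horizon ``T`` for instantaneous estimates, and ``T - window`` for
integrated estimates (whose reference is the window-averaged forced diet).

Sweep helpers run the forward model over grids of switch frequency, rate
and window multiplier, with replicated Brownian source pairs, and collect
per-cell mean/sd bias tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidInputError
from .forcing import (
    BrownianSpec,
    DietSchedule,
    SourcePool,
    TurnoverSchedule,
    constant_sources,
    diet_switch_schedule,
    make_turnover,
    simulate_brownian_sources,
)
from .dmm import integrate_consumer
from .smm import DietEstimate, reference_diet_windowed, smm_instant, smm_integrated

__all__ = [
    "compute_bias",
    "sweep_ratio",
    "sweep_window_multiplier",
    "sweep_omega_lambda_grid",
    "run_scenario_set",
    "FIG5_RATIOS",
]

#: ratio grid of the headline sweep: 0.01 then 0.5 .. 4.0 in steps of 0.5
FIG5_RATIOS = (0.01, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

_TIME_TOL = 1e-9


def _reference_values(reference, estimate: DietEstimate) -> np.ndarray:
    if isinstance(reference, DietSchedule):
        if estimate.method == "SMM_Dt":
            raise InvalidInputError(
                "integrated estimates need a window-averaged reference; "
                "pass the output of reference_diet_windowed"
            )
        return np.asarray(reference.proportion(0, estimate.times), dtype=float)
    if isinstance(reference, DietEstimate):
        idx = np.searchsorted(reference.times, estimate.times)
        idx = np.clip(idx, 0, reference.times.size - 1)
        if np.any(np.abs(reference.times[idx] - estimate.times) > _TIME_TOL):
            raise AlignmentError(
                "reference and estimate do not share a common time grid"
            )
        return reference.p_hat[idx]
    raise InvalidInputError(f"unsupported reference type {type(reference)!r}")


def compute_bias(reference, estimate: DietEstimate) -> float:
    """Mean absolute proportion error of an estimate against its reference.

    ``reference`` is a :class:`DietSchedule` (instantaneous estimates) or a
    :class:`DietEstimate` covering the estimate's emitted times (e.g. the
    window-averaged forced diet for integrated estimates).  The sum of
    absolute differences is divided by the spanned time: ``T`` for
    instantaneous grids starting at 0, ``T - window`` for integrated ones.
    """
    if estimate.times.size == 0:
        raise InvalidInputError("estimate is empty")
    ref = _reference_values(reference, estimate)
    total = float(np.sum(np.abs(ref - estimate.p_hat)))
    t_last = float(estimate.times[-1])
    if estimate.method == "SMM_Dt" and estimate.window is not None:
        w = np.asarray(estimate.window, dtype=float)
        if np.allclose(w, w[0]):
            denom = t_last - float(w[0])
        else:
            denom = t_last - float(estimate.times[0])
    else:
        denom = t_last - float(estimate.times[0])
        if denom <= 0:
            denom = float(estimate.times.size)
    if denom <= 0:
        raise InvalidInputError("estimate span is too short for the bias sum")
    return total / denom


def _replicate_pools(
    source_mode: str,
    n_replicates: int,
    seed: int,
    horizon: float,
    step_variance: float,
    tdfs: tuple[float, float],
    n_candidates: int | None,
    constant_values: tuple[float, float] = (0.0, 10.0),
) -> list[SourcePool]:
    if source_mode == "constant":
        return [constant_sources(constant_values, tdfs, horizon)]
    if source_mode == "brownian":
        if n_candidates is None:
            # pairwise 2-permil filtering rejects roughly half the candidate
            # pairs at the default variance; oversample accordingly
            n_candidates = max(3 * n_replicates, 30)
        spec = BrownianSpec(
            initial_values=constant_values,
            step_variance=step_variance,
            n_candidates=n_candidates,
            n_keep=n_replicates,
            seed=seed,
        )
        return simulate_brownian_sources(spec, horizon, tdfs=tdfs)
    raise InvalidInputError(f"unknown source mode {source_mode!r}")


def _bias_for_method(
    method: str,
    traj,
    pool: SourcePool,
    schedule: DietSchedule,
    turnover: TurnoverSchedule,
    window_multiplier: float,
) -> float:
    if method == "smm_t":
        est = smm_instant(traj.consumer, pool)
        return compute_bias(schedule, est)
    if method == "smm_dt":
        est = smm_integrated(traj.consumer, pool, turnover, window_multiplier)
        ref = reference_diet_windowed(
            schedule, turnover, window_multiplier, times=traj.consumer.times
        )
        return compute_bias(ref, est)
    raise InvalidInputError(f"unknown method {method!r}")


def sweep_ratio(
    omegas,
    lam: float = 0.02,
    source_mode: str = "brownian",
    n_replicates: int = 100,
    seed: int = 0,
    methods=("smm_t", "smm_dt"),
    horizon: float = 500.0,
    window_multiplier: float = 2.0,
    turnover: TurnoverSchedule | None = None,
    turnover_mode: str = "constant",
    step_variance: float = 0.2,
    tdfs: tuple[float, float] = (1.0, 1.0),
    n_candidates: int | None = None,
) -> pd.DataFrame:
    """Bias of each method across switch frequencies at a fixed rate.

    Returns one row per (omega, method) with the replicate mean and sd of
    the bias.  For constant sources there is a single deterministic
    replicate.
    """
    if turnover is None:
        turnover = make_turnover("constant", lambda0=lam)
    pools = _replicate_pools(
        source_mode, n_replicates, seed, horizon, step_variance, tdfs, n_candidates
    )
    rows = []
    for omega in omegas:
        schedule = diet_switch_schedule(float(omega), horizon)
        biases = {m: [] for m in methods}
        for pool in pools:
            traj = integrate_consumer(pool, schedule, turnover, horizon)
            for m in methods:
                biases[m].append(
                    _bias_for_method(
                        m, traj, pool, schedule, turnover, window_multiplier
                    )
                )
        for m in methods:
            vals = np.asarray(biases[m])
            rows.append(
                {
                    "ratio": float(omega) / lam,
                    "omega": float(omega),
                    "lam": lam,
                    "method": {"smm_t": "SMM_t", "smm_dt": "SMM_Dt"}[m],
                    "source_mode": source_mode,
                    "turnover_mode": turnover_mode,
                    "bias_mean": float(vals.mean()),
                    "bias_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n_replicates": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def sweep_window_multiplier(
    multipliers=(0.5, 1.0, 2.0, 3.0),
    omegas=None,
    lam: float = 0.02,
    source_mode: str = "brownian",
    n_replicates: int = 20,
    seed: int = 0,
    horizon: float = 500.0,
    step_variance: float = 0.2,
    tdfs: tuple[float, float] = (1.0, 1.0),
    n_candidates: int | None = None,
) -> pd.DataFrame:
    """Integrated-estimator bias per window multiplier across the ratio grid.

    Simulations are shared across multipliers (only the inference window
    changes), so the table is internally comparable.
    """
    if omegas is None:
        omegas = tuple(r * lam for r in FIG5_RATIOS)
    turnover = make_turnover("constant", lambda0=lam)
    pools = _replicate_pools(
        source_mode, n_replicates, seed, horizon, step_variance, tdfs, n_candidates
    )
    rows = []
    for omega in omegas:
        schedule = diet_switch_schedule(float(omega), horizon)
        trajs = [
            integrate_consumer(pool, schedule, turnover, horizon) for pool in pools
        ]
        for mult in multipliers:
            vals = []
            for pool, traj in zip(pools, trajs):
                vals.append(
                    _bias_for_method(
                        "smm_dt", traj, pool, schedule, turnover, float(mult)
                    )
                )
            vals = np.asarray(vals)
            rows.append(
                {
                    "ratio": float(omega) / lam,
                    "omega": float(omega),
                    "lam": lam,
                    "method": "SMM_Dt",
                    "window_multiplier": float(mult),
                    "source_mode": source_mode,
                    "turnover_mode": "constant",
                    "bias_mean": float(vals.mean()),
                    "bias_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n_replicates": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def sweep_omega_lambda_grid(
    omegas,
    lambdas,
    source_mode: str = "constant",
    n_replicates: int = 20,
    seed: int = 0,
    methods=("smm_t",),
    horizon: float = 500.0,
    step_variance: float = 0.2,
    tdfs: tuple[float, float] = (1.0, 1.0),
    n_candidates: int | None = None,
) -> pd.DataFrame:
    """Full factorial (omega, lambda) bias table."""
    frames = []
    for lam in lambdas:
        frames.append(
            sweep_ratio(
                omegas,
                lam=float(lam),
                source_mode=source_mode,
                n_replicates=n_replicates,
                seed=seed,
                methods=methods,
                horizon=horizon,
                step_variance=step_variance,
                tdfs=tdfs,
                n_candidates=n_candidates,
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_scenario_set(
    set_id: int,
    seed: int = 0,
    n_replicates: int = 10,
    horizon: float = 500.0,
):
    """Run one of the three canonical scenario sets of increasing complexity.

    Set 1: constant sources, omega in {0.002, 0.008} x constant lambda in
    {0.002, 0.02, 0.2}.  Set 2: the same switching grid with Brownian
    sources.  Set 3: Brownian sources with the ontogenetic (exponentially
    decaying) rate.  Returns a dict with per-combination trajectories,
    instantaneous estimates, and a bias table.
    """
    omegas = (0.002, 0.008)
    lams = (0.002, 0.02, 0.2)
    if set_id == 1:
        pools = {None: constant_sources((0.0, 10.0), (1.0, 1.0), horizon)}
        source_mode = "constant"
        turnovers = {lam: make_turnover("constant", lambda0=lam) for lam in lams}
    elif set_id == 2:
        spec = BrownianSpec(
            n_candidates=max(3 * n_replicates, 30), n_keep=n_replicates, seed=seed
        )
        pools = dict(enumerate(simulate_brownian_sources(spec, horizon)))
        source_mode = "brownian"
        turnovers = {lam: make_turnover("constant", lambda0=lam) for lam in lams}
    elif set_id == 3:
        spec = BrownianSpec(
            n_candidates=max(3 * n_replicates, 30), n_keep=n_replicates, seed=seed
        )
        pools = dict(enumerate(simulate_brownian_sources(spec, horizon)))
        source_mode = "brownian"
        turnovers = {
            "ontogenetic": make_turnover("exponential", lambda0=0.2, alpha=0.01)
        }
        omegas = (0.008,)
    else:
        raise InvalidInputError(f"unknown scenario set {set_id!r}")

    trajectories = {}
    estimates = {}
    rows = []
    for omega in omegas:
        schedule = diet_switch_schedule(omega, horizon)
        for key, turnover in turnovers.items():
            biases = []
            for pool_key, pool in pools.items():
                traj = integrate_consumer(pool, schedule, turnover, horizon)
                est = smm_instant(traj.consumer, pool)
                biases.append(compute_bias(schedule, est))
                if pool_key in (None, 0):
                    trajectories[(omega, key)] = traj
                    estimates[(omega, key)] = est
            vals = np.asarray(biases)
            lam_value = turnover.lambda0 if turnover.mode == "constant" else None
            rows.append(
                {
                    "ratio": omega / lam_value if lam_value else float("nan"),
                    "omega": omega,
                    "lam": lam_value,
                    "method": "SMM_t",
                    "source_mode": source_mode,
                    "turnover_mode": (
                        "constant" if turnover.mode == "constant" else "ontogenetic"
                    ),
                    "bias_mean": float(vals.mean()),
                    "bias_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n_replicates": int(vals.size),
                }
            )
    return {
        "trajectories": trajectories,
        "estimates": estimates,
        "bias": pd.DataFrame(rows),
    }
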