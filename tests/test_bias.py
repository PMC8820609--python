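import math

import numpy as np
import pandas as pd
import pytest

from isomix import (
    FIG5_RATIOS,
    compute_bias,
    diet_switch_schedule,
    run_scenario_set,
    sweep_omega_lambda_grid,
    sweep_ratio,
    sweep_window_multiplier,
)
from isomix.errors import AlignmentError, InvalidInputError
from isomix.smm import DietEstimate


def estimate(times, p_hat, method="SMM_t", window=None):
    return DietEstimate(method, np.asarray(times, float), np.asarray(p_hat, float),
                        np.empty(0), window=window)


class TestComputeBias:
    def test_zero_bias_identity(self):
        ref = estimate(np.arange(5.0), [1, 1, 0, 0, 1])
        est = estimate(np.arange(5.0), [1, 1, 0, 0, 1])
        assert compute_bias(ref, est) == 0.0

    def test_constant_offset(self):
        t = np.arange(0.0, 500.0)
        ref = estimate(t, np.ones(t.size))
        est = estimate(t, np.full(t.size, 0.5))
        # 500 samples of 0.5 over a 499-day span
        assert compute_bias(ref, est) == pytest.approx(0.5 * 500 / 499)

    def test_hand_sum(self):
        # hand sum 1.2 over the 4-day span of the grid 0..4
        ref = estimate(np.arange(5.0), [1, 1, 0, 0, 1])
        est = estimate(np.arange(5.0), [0.9, 0.8, 0.1, 0.3, 0.5])
        assert compute_bias(ref, est) == pytest.approx(1.2 / 4.0)

    def test_bounded_by_max_step_difference(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 100.0)
        a, b = rng.uniform(0, 1, t.size), rng.uniform(0, 1, t.size)
        bias = compute_bias(estimate(t, a), estimate(t, b))
        assert bias <= np.max(np.abs(a - b)) * t.size / (t.size - 1) + 1e-12

    def test_symmetry(self):
        t = np.arange(0.0, 50.0)
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, t.size), rng.uniform(0, 1, t.size)
        assert compute_bias(estimate(t, a), estimate(t, b)) == pytest.approx(
            compute_bias(estimate(t, b), estimate(t, a))
        )

    def test_integrated_denominator(self):
        # emitted times 70..500 with a 69.31 d window: divide by T - window
        w = 2 * math.log(2) / 0.02
        t = np.arange(70.0, 501.0)
        ref = estimate(t, np.ones(t.size))
        est = estimate(t, np.zeros(t.size), method="SMM_Dt",
                       window=np.full(t.size, w))
        assert compute_bias(ref, est) == pytest.approx(t.size / (500.0 - w))

    def test_schedule_reference(self):
        sched = diet_switch_schedule(0.008, 500.0)
        t = np.arange(0.0, 501.0)
        est = estimate(t, sched.proportion(0, t))
        assert compute_bias(sched, est) == 0.0

    def test_schedule_reference_rejected_for_integrated(self):
        sched = diet_switch_schedule(0.008, 500.0)
        t = np.arange(70.0, 501.0)
        est = estimate(t, np.ones(t.size), method="SMM_Dt",
                       window=np.full(t.size, 69.3))
        with pytest.raises(InvalidInputError):
            compute_bias(sched, est)

    def test_disjoint_grids_error(self):
        ref = estimate(np.arange(0.0, 10.0), np.ones(10))
        est = estimate(np.arange(0.0, 10.0) + 0.5, np.ones(10))
        with pytest.raises(AlignmentError):
            compute_bias(ref, est)


@pytest.fixture(scope="module")
def constant_sweep():
    omegas = [r * 0.02 for r in FIG5_RATIOS]
    return sweep_ratio(omegas, lam=0.02, source_mode="constant")


class TestSweepRatio:
    def test_ratio_grid(self, constant_sweep):
        ratios = sorted(set(constant_sweep["ratio"].round(6)))
        assert ratios == [0.01, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]

    def test_low_ratio_instantaneous_bias_closed_form(self, constant_sweep):
        # single switch at t=0: |p - p_hat| = exp(-lam*t) for t >= 1, so the
        # bias is a geometric sum over the daily grid divided by T
        lam, T = 0.02, 500
        expected = (
            math.exp(-lam) * (1 - math.exp(-lam * T)) / (1 - math.exp(-lam))
        ) / T
        row = constant_sweep.query("ratio == 0.01 and method == 'SMM_t'")
        assert row["bias_mean"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_instantaneous_plateau(self, constant_sweep):
        smm_t = constant_sweep.query("method == 'SMM_t'").set_index("ratio")
        assert smm_t.loc[1.0:, "bias_mean"].min() > 0.4
        assert smm_t["bias_mean"].max() < 0.55

    def test_improvement_property(self, constant_sweep):
        p = constant_sweep.pivot(index="ratio", columns="method",
                                 values="bias_mean")
        high = p.loc[0.5:]
        assert np.all(high["SMM_Dt"] <= high["SMM_t"])

    def test_integrated_peak_low_ratio(self, constant_sweep):
        smm_dt = constant_sweep.query("method == 'SMM_Dt'").set_index("ratio")
        assert smm_dt["bias_mean"].idxmax() == 0.5
        assert smm_dt["bias_mean"].max() < 0.15

    def test_equal_ratio_pairs_deterministic(self):
        a = sweep_ratio([0.008], lam=0.02, source_mode="constant",
                        methods=("smm_t",))
        b = sweep_ratio([0.04], lam=0.1, source_mode="constant",
                        methods=("smm_t",))
        assert abs(a["bias_mean"].iloc[0] - b["bias_mean"].iloc[0]) < 0.02

    def test_brownian_seed_determinism(self):
        kwargs = dict(lam=0.02, source_mode="brownian", n_replicates=3, seed=5,
                      methods=("smm_t",))
        a = sweep_ratio([0.01, 0.04], **kwargs)
        b = sweep_ratio([0.01, 0.04], **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_method_errors(self):
        with pytest.raises(InvalidInputError):
            sweep_ratio([0.01], source_mode="constant", methods=("bogus",))

    def test_unknown_source_mode_errors(self):
        with pytest.raises(InvalidInputError):
            sweep_ratio([0.01], source_mode="levy")


class TestWindowMultiplierSweep:
    def test_multiplier_two_is_minimax(self):
        df = sweep_window_multiplier(source_mode="constant", n_replicates=1)
        worst = df.groupby("window_multiplier")["bias_mean"].max()
        assert worst.idxmin() == 2.0

    def test_small_multiplier_approaches_instantaneous(self):
        df = sweep_window_multiplier(
            multipliers=(1e-9,), omegas=(0.01,), source_mode="constant",
            n_replicates=1,
        )
        inst = sweep_ratio([0.01], lam=0.02, source_mode="constant",
                           methods=("smm_t",))
        assert df["bias_mean"].iloc[0] == pytest.approx(
            inst["bias_mean"].iloc[0], abs=1e-3
        )

    def test_mini_sweep_reproducible(self):
        kwargs = dict(multipliers=(1.0, 2.0), omegas=(0.01, 0.02, 0.04),
                      source_mode="brownian", n_replicates=3, seed=7)
        a = sweep_window_multiplier(**kwargs)
        b = sweep_window_multiplier(**kwargs)
        pd.testing.assert_frame_equal(a, b)


class TestOmegaLambdaGrid:
    def test_factorial_shape(self):
        df = sweep_omega_lambda_grid(
            (0.008, 0.02), (0.02, 0.1), source_mode="constant"
        )
        assert len(df) == 4
        assert set(df["lam"]) == {0.02, 0.1}

    def test_bias_increases_with_omega_at_fixed_lambda(self):
        df = sweep_omega_lambda_grid((0.002, 0.02), (0.02,),
                                     source_mode="constant")
        by_omega = df.set_index("omega")["bias_mean"]
        assert by_omega[0.02] > by_omega[0.002]

    def test_bias_increases_when_lambda_decreases_at_fixed_omega(self):
        df = sweep_omega_lambda_grid((0.008,), (0.002, 0.2),
                                     source_mode="constant")
        by_lam = df.set_index("lam")["bias_mean"]
        assert by_lam[0.002] > by_lam[0.2]


class TestScenarioSets:
    def test_set1_slow_turnover_never_equilibrates(self):
        out = run_scenario_set(1)
        traj = out["trajectories"][(0.002, 0.002)]
        assert abs(traj.consumer.values[-1] - traj.diet_target.values[-1]) > 1.0

    def test_set1_fast_switching_tends_to_midpoint(self):
        out = run_scenario_set(1)
        traj = out["trajectories"][(0.008, 0.002)]
        # deviation from the corrected-source midpoint shrinks step by step
        deviations = [
            abs(traj.consumer.at(t) - 6.0) for t in (0.0, 250.0, 500.0)
        ]
        assert deviations[0] > deviations[1] > deviations[2]
        assert deviations[2] < 2.5

    def test_set2_runs_with_brownian_sources(self):
        out = run_scenario_set(2, seed=3, n_replicates=3)
        assert len(out["bias"]) == 6
        assert (out["bias"]["n_replicates"] == 3).all()

    def test_set3_ratio_span(self):
        out = run_scenario_set(3, seed=3, n_replicates=2)
        traj = out["trajectories"][(0.008, "ontogenetic")]
        lam_t = 0.2 * np.exp(-0.01 * traj.consumer.times)
        ratios = 0.008 / lam_t
        assert ratios.min() == pytest.approx(0.04, rel=1e-6)
        assert 5.8 < ratios.max() < 6.1

    def test_unknown_set_errors(self):
        with pytest.raises(InvalidInputError):
            run_scenario_set(4)
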