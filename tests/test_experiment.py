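"""Tests for the trial loop, binned metrics, replications and sweeps."""

import numpy as np
import pandas as pd
import pytest

from syncgate import experiment, tasks
from syncgate.experiment import (BinnedMetrics, SimParams,
                                 aggregate_replications, bin_metrics,
                                 bursting_synchrony_demo, default_bin_count,
                                 run_replications, run_simulation,
                                 sweep_learning_rate)


def _records_with_accuracy(acc: np.ndarray, n_blocks: int = 6) -> pd.DataFrame:
    n = acc.size
    return pd.DataFrame({
        "block": np.repeat(np.arange(n_blocks), n // n_blocks),
        "accuracy": acc,
    })


class TestBinMetrics:
    def test_bin_size_from_trial_count(self):
        rec = _records_with_accuracy(np.ones(360))
        m = bin_metrics(rec)
        assert m.bin_size == 3
        assert m.accuracy.size == 120

    def test_identical_paired_bins_give_zero_stability(self):
        rec = _records_with_accuracy(np.full(360, 0.7))
        assert bin_metrics(rec).stability == pytest.approx(0.0)

    def test_forgetting_arithmetic(self):
        # perfect at block ends, chance on re-entry: stability = 1/3 - 1
        acc = np.full(360, 0.5)
        for b in range(3):                      # last 5 bins (15 trials)
            acc[(b + 1) * 60 - 15:(b + 1) * 60] = 1.0
        for b in range(3, 6):                   # first 5 bins of re-entry
            acc[b * 60:b * 60 + 15] = 1.0 / 3.0
        m = bin_metrics(_records_with_accuracy(acc))
        assert m.stability == pytest.approx(1.0 / 3.0 - 1.0)

    def test_plasticity_window(self):
        acc = np.zeros(360)
        for b in range(3):
            acc[b * 60:b * 60 + 15] = 1.0       # first 5 bins of blocks 1-3
        m = bin_metrics(_records_with_accuracy(acc))
        assert m.plasticity == pytest.approx(1.0)

    def test_indivisible_count_rejected(self):
        with pytest.raises(ValueError):
            bin_metrics(_records_with_accuracy(np.ones(360)), n_bins=77)

    def test_score_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = bin_metrics(_records_with_accuracy(rng.random(360)))
            assert 0.0 <= m.plasticity <= 1.0
            assert -1.0 <= m.stability <= 1.0


class TestDefaultBinCount:
    @pytest.mark.parametrize("n,expected", [(360, 120), (3600, 120),
                                            (1200, 120), (120, 120), (60, 60)])
    def test_values(self, n, expected):
        assert default_bin_count(n) == expected
        assert n % default_bin_count(n) == 0


class TestRunSimulation:
    def test_determinism(self):
        task = tasks.make_one_dim_task(4, n_trials=120)
        a = run_simulation("rw-full", task, 0.2, seed=9)
        b = run_simulation("rw-full", task, 0.2, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_beta_zero_freezes_weights_and_accuracy(self):
        task = tasks.make_one_dim_task(0, n_trials=120)
        res = run_simulation("rw-full", task, beta=0.0, seed=3,
                             record_weight_change=True)
        assert np.all(res.weight_change == 0.0)
        assert 0.1 < res.accuracy < 0.6          # chance-level, no learning

    def test_invalid_model_kind(self):
        task = tasks.make_one_dim_task(0, n_trials=60)
        with pytest.raises(ValueError):
            run_simulation("hopfield-full", task)

    def test_beta_out_of_range(self):
        task = tasks.make_one_dim_task(0, n_trials=60)
        with pytest.raises(ValueError):
            run_simulation("rw-full", task, beta=1.5)

    def test_nosync_has_no_control_unit(self):
        task = tasks.make_one_dim_task(1, n_trials=60)
        res = run_simulation("rw-nosync", task, 0.5, seed=1)
        assert not res.records.switch.any()
        assert res.records.v.isna().all()
        assert (res.records.module == -1).all()

    def test_nosync_rw_learns_fast(self):
        task = tasks.make_one_dim_task(2, n_trials=120)
        res = run_simulation("rw-nosync", task, 0.5, seed=2)
        late = res.records[res.records.trial % 20 >= 10]
        assert late.accuracy.mean() > 0.8

    def test_traces_shape(self):
        task = tasks.make_one_dim_task(0, n_trials=12, n_blocks=6)
        res = run_simulation("rw-full", task, 0.2, seed=0,
                             record_traces=True)
        assert res.proc_E.shape == (12 * 500, 12)   # 3 inputs + 9 module nodes
        assert res.pmfc_E.shape == (12 * 500,)

    def test_full_rw_responds_via_learned_mapping(self):
        # after learning rule A, showing feature f yields response f
        task = tasks.make_one_dim_task(5)
        res = run_simulation("rw-full", task, 0.2, seed=5)
        last_block1 = res.records[(res.records.block == 0)].tail(15)
        assert (last_block1.response == last_block1.f0).mean() > 0.8


class TestReplicationsAndAggregation:
    def test_replication_count_and_independence(self):
        runs = run_replications("rw-nosync",
                                lambda s: tasks.make_one_dim_task(s, 60),
                                beta=0.3, n_reps=3, seed=0)
        assert len(runs) == 3
        assert len({r.seed for r in runs}) == 3

    def test_ci_shrinks_with_replications(self):
        rng = np.random.default_rng(1)
        mk = lambda n: [BinnedMetrics(rng.random(60), 6, 10, 6)
                        for _ in range(n)]
        wide = aggregate_replications(mk(4))
        narrow = aggregate_replications(mk(64))
        assert narrow["accuracy_ci"].mean() < wide["accuracy_ci"].mean()

    def test_single_rep_ci_is_zero(self):
        agg = aggregate_replications([BinnedMetrics(np.ones(60), 6, 10, 6)])
        assert agg["plasticity_ci"] == 0.0


class TestSweeps:
    def test_learning_rate_grid_shape(self):
        table = sweep_learning_rate(
            "rw-nosync", lambda s: tasks.make_one_dim_task(s, 60),
            betas=[0.0, 0.5, 1.0], n_reps=2, seed=0, n_bins=60)
        assert len(table) == 6
        assert set(table.beta) == {0.0, 0.5, 1.0}
        assert {"accuracy", "plasticity", "stability"} <= set(table.columns)

    def test_default_grid_is_eleven_steps(self):
        betas = np.round(np.linspace(0.0, 1.0, 11), 10)
        assert betas.size == 11
        assert betas[1] == pytest.approx(0.1)

    def test_fast_controller_degrades_accuracy(self):
        # bursting faster than the processing rhythm floods the network
        # with noise: accuracy collapses toward chance
        table = experiment.sweep_oscillator_params(
            ctrl_freqs=[5.0, 40.0], proc_freqs=[40.0],
            ctrl_damps=[0.003], ctrl_r_mins=[0.05],
            task_maker=lambda s: tasks.make_one_dim_task(s, 120),
            n_reps=2, seed=0)
        acc = table.groupby("ctrl_freq").accuracy.mean()
        assert acc[5.0] > acc[40.0]


class TestSynchronyDemo:
    def test_bursting_binds_and_unbinds(self):
        c_pointed, c_anti = bursting_synchrony_demo(seed=1)
        assert c_pointed > 0.8
        assert c_anti < -0.8

    def test_without_bursts_phases_stay_random(self):
        c_pointed, c_anti = bursting_synchrony_demo(seed=1, pmfc_radius=0.05)
        # controller at rest emits essentially no bursts: no binding
        assert abs(c_pointed) < 0.8 or abs(c_anti) < 0.8
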