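"""Tests for the processing network: weights, forward dynamics, learning."""

import numpy as np
import pytest

from syncgate.control import LFCState
from syncgate.oscillator import gamma_params
from syncgate.processing import (Network, NetworkSpec, bp_weight_deltas,
                                 rw_classic_delta, rw_modified_delta,
                                 static_mlp_forward)


@pytest.fixture
def rng():
    return np.random.default_rng(12)


class TestInitWeights:
    def test_bp_range(self, rng):
        net = Network(NetworkSpec.bp_full(12), rng)
        for w in (net.w1, net.w2):
            assert w.min() >= 0.0 and w.max() <= 2.5

    def test_rw_range(self, rng):
        net = Network(NetworkSpec.rw_full(), rng)
        assert net.w1.min() >= 0.0 and net.w1.max() <= 1.0
        assert net.w2 is None

    def test_seed_determinism(self):
        a = Network(NetworkSpec.bp_full(12), np.random.default_rng(5))
        b = Network(NetworkSpec.bp_full(12), np.random.default_rng(5))
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.w2, b.w2)


class TestSpecValidation:
    def test_rw_has_no_output_layer(self):
        with pytest.raises(ValueError):
            NetworkSpec("rw", True, 3, 3, 3, 3)

    def test_bp_needs_output_layer(self):
        with pytest.raises(ValueError):
            NetworkSpec("bp", True, 12, 3, 4, 0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            NetworkSpec.for_kind("rbm-full", 3)


class TestForward:
    def test_no_stimulus_silent(self, rng):
        net = Network(NetworkSpec.rw_full(), rng, gamma_params())
        net.set_module_pointers(np.array([1.0, -1.0, -1.0]))
        net.begin_trial()
        for _ in range(500):
            net.step(None, 0, 0.0)
        assert net.X_l2.max() == pytest.approx(0.0, abs=1e-12)

    def test_bp_floor_without_input(self, rng):
        # sigmoid nodes rest near f(-bias) times the maximal gate
        net = Network(NetworkSpec.bp_nosync(12), rng)
        net.begin_trial()
        for _ in range(100):
            net.step(None)
        # hidden nodes rest at f(-bias); outputs just above, at
        # f(W2 @ f(-bias) - bias)
        floor = 1.0 / (1.0 + np.exp(5.0))
        assert net.X_l2.max() <= floor + 1e-9
        out_ceiling = 1.0 / (1.0 + np.exp(-(net.w2.sum(axis=1).max() * floor - 5.0)))
        assert net.X_out.max() <= out_ceiling + 1e-9

    def test_nosync_gains_are_unity(self, rng):
        # without phase codes a constant input passes through at full drive
        net = Network(NetworkSpec.rw_nosync(), rng)
        net.begin_trial()
        stim = np.array([1.0, 0.0, 0.0])
        for _ in range(10):
            net.step(stim)
        np.testing.assert_allclose(net.X_in, stim)
        np.testing.assert_allclose(net.X_l2, net.w1 @ stim)

    def test_gated_out_module_is_quiet(self, rng):
        """Anti-phase module transmits < 10% of the pointed module."""
        net = Network(NetworkSpec.rw_full(), rng, gamma_params())
        # deterministic phases: inputs and module 0 in phase, others anti
        n_in, n_l2 = 3, 9
        net.E[:] = -1.0
        net.I[:] = 0.0
        net.E[:n_in] = 1.0
        net.E[n_in:n_in + 3] = 1.0
        net.w1[:] = 1.0
        net.begin_trial()
        stim = np.array([1.0, 1.0, 1.0])
        for _ in range(500):
            net.step(stim, 0, 0.0)
        x_pointed = net.X_l2[:3].mean()
        x_anti = net.X_l2[3:].mean()
        assert x_anti < 0.10 * x_pointed


class TestReadout:
    def test_argmax_and_tiebreak(self, rng):
        net = Network(NetworkSpec.bp_full(12), rng)
        net.X_out = np.array([0.1, 0.9, 0.2])
        assert net.readout() == 1
        net.X_out = np.array([0.4, 0.4, 0.4])
        assert net.readout() == 0

    def test_rw_pools_modules_by_max(self, rng):
        net = Network(NetworkSpec.rw_full(), rng, gamma_params())
        x = np.zeros(9)
        x[2] = 0.5          # module 0 votes response 2
        x[3] = 0.05         # gated-out module 1 weakly votes response 0
        net.X_l2 = x
        assert net.readout() == 2


class TestLearningRules:
    def test_modified_rule_needs_coactivation(self):
        x_in = np.array([1.0, 0.0])
        x_out = np.array([0.0, 0.5])
        t = np.array([1.0, 1.0])
        dw = rw_modified_delta(x_in, x_out, t, beta=0.2)
        assert np.all(dw[0] == 0.0)                    # X_o = 0: ineligible
        assert dw[1, 0] == pytest.approx(0.05)         # .2 * .5 * 1 * .5

    def test_zero_error_is_stationary(self):
        x_in = np.array([0.8])
        x_out = np.array([0.3])
        t = np.array([0.3])
        assert np.all(rw_modified_delta(x_in, x_out, t, 0.5) == 0.0)
        assert np.all(rw_classic_delta(x_in, x_out, t, 0.5) == 0.0)

    def test_classic_rule_value(self):
        dw = rw_classic_delta(np.array([1.0]), np.array([0.5]),
                              np.array([1.0]), beta=0.2)
        assert dw[0, 0] == pytest.approx(0.1)

    def test_rules_differ_by_output_factor(self):
        rng = np.random.default_rng(0)
        x_in = rng.random(4)
        x_out = rng.random(3)
        t = rng.random(3)
        classic = rw_classic_delta(x_in, x_out, t, 0.3)
        modified = rw_modified_delta(x_in, x_out, t, 0.3)
        np.testing.assert_allclose(modified, classic * x_out[:, None])

    def test_bp_zero_at_target(self):
        rng = np.random.default_rng(1)
        w2 = rng.random((3, 4))
        x_o = np.array([0.2, 0.7, 0.5])
        dw1, dw2 = bp_weight_deltas(rng.random(5), rng.random(4), x_o, w2,
                                    x_o.copy(), 0.2)
        assert np.allclose(dw1, 0.0) and np.allclose(dw2, 0.0)

    def test_bp_saturated_output_has_zero_delta(self):
        rng = np.random.default_rng(2)
        w2 = rng.random((2, 3))
        x_o = np.array([0.0, 1.0])
        t = np.array([1.0, 0.0])
        dw1, dw2 = bp_weight_deltas(rng.random(4), rng.random(3), x_o, w2, t, 1.0)
        assert np.allclose(dw2, 0.0) and np.allclose(dw1, 0.0)


class TestBPGradientCheck:
    def test_matches_finite_differences(self):
        """Analytic trial-level BP step equals the centered finite-difference
        gradient of the squared error on the static (gain = 1) network."""
        rng = np.random.default_rng(42)
        n_in, n_h, n_out = 6, 5, 3
        w1 = rng.uniform(0, 2.5, (n_h, n_in))
        w2 = rng.uniform(0, 2.5, (n_out, n_h))
        x = rng.integers(0, 2, n_in).astype(float)
        t = np.zeros(n_out)
        t[1] = 1.0
        beta = 1.0

        x_h, x_o = static_mlp_forward(w1, w2, x)
        dw1, dw2 = bp_weight_deltas(x, x_h, x_o, w2, t, beta)

        def loss(w1_, w2_):
            _, o = static_mlp_forward(w1_, w2_, x)
            return 0.5 * np.sum((t - o) ** 2)

        eps = 1e-6
        for (analytic, w, other, first) in ((dw1, w1, w2, True),
                                            (dw2, w2, w1, False)):
            num = np.zeros_like(w)
            for idx in np.ndindex(w.shape):
                wp, wm = w.copy(), w.copy()
                wp[idx] += eps
                wm[idx] -= eps
                if first:
                    num[idx] = (loss(wp, other) - loss(wm, other)) / (2 * eps)
                else:
                    num[idx] = (loss(other, wp) - loss(other, wm)) / (2 * eps)
            # gradient descent step: analytic = -beta * dL/dW
            scale = np.max(np.abs(num))
            np.testing.assert_allclose(analytic, -beta * num,
                                       atol=1e-4 * scale)


def test_learning_reports_per_module_change(rng):
    net = Network(NetworkSpec.rw_full(), rng, gamma_params())
    net.X_in = np.array([1.0, 0.0, 0.0])
    net.X_l2 = np.zeros(9)
    net.X_l2[0] = 0.5     # only module 0 active
    target = np.array([1.0, 0.0, 0.0])
    totals = net.learn(target, beta=0.2)
    assert totals[0] > 0.0
    assert totals[1] == totals[2] == 0.0


def test_rbm_hook_is_declared_but_not_implemented():
    from syncgate.processing import learn_rbm_step
    with pytest.raises(NotImplementedError):
        learn_rbm_step()
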