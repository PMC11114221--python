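"""Device-aware perceptron: forward/backward oracles, bounds, training."""

import numpy as np
import pytest

from aosim import (
    AnnConfig,
    DeviceParams,
    SINGLE_CLASSES,
    build_datasets,
    evaluate,
    forward,
    init_network,
    linearity_sweep,
    synapse_count,
    train,
    train_step,
    weight_of,
)
from aosim.ann import _sigmoid, backprop_deltas, state_from_json
from aosim.refine import PatternDataset


def _random_pattern(rng, n_regions=9):
    grid = np.zeros((n_regions, 3), dtype=int)
    for c in range(3):
        grid[rng.integers(n_regions), c] = 1
    return grid.reshape(-1).astype(float)


@pytest.fixture(scope="module")
def single_sets(profile):
    _, train_set, infer_set = build_datasets(profile, SINGLE_CLASSES, 216, 40, seed=1)
    return train_set, infer_set


class TestInit:
    def test_pair_shapes_and_synapse_count(self, device):
        cfg = AnnConfig()
        state = init_network(cfg, device, seed=0)
        assert state.p1_plus.shape == (27, 14)
        assert state.p2_plus.shape == (14, 4)
        # the product convention counts 27*14*4 = 1512 synapses
        assert synapse_count(cfg) == 1512

    def test_same_seed_identical_weights(self, device):
        cfg = AnnConfig()
        w1a, w2a = init_network(cfg, device, seed=5).weights()
        w1b, w2b = init_network(cfg, device, seed=5).weights()
        np.testing.assert_array_equal(w1a, w1b)
        np.testing.assert_array_equal(w2a, w2b)

    def test_initial_weights_within_configured_scales(self, device):
        cfg = AnnConfig()
        w1, w2 = init_network(cfg, device, seed=3).weights()
        # pulse quantization can overshoot by at most one pulse (~1/p_max)
        tol = 1.5 / device.p_max
        assert np.max(np.abs(w1)) <= cfg.init_scale_input + tol
        assert np.max(np.abs(w2)) <= cfg.init_scale_output + tol


class TestWeightOf:
    def test_identities(self, device):
        assert weight_of(device.g_min, device.g_min, device) == 0.0
        assert weight_of(device.g_max, device.g_min, device) == pytest.approx(1.0)
        assert weight_of(device.g_min, device.g_max, device) == pytest.approx(-1.0)

    def test_antisymmetric_under_swap(self, device):
        rng = np.random.default_rng(0)
        g = rng.uniform(device.g_min, device.g_max, size=(2, 20))
        np.testing.assert_allclose(
            weight_of(g[0], g[1], device), -weight_of(g[1], g[0], device)
        )

    def test_out_of_bounds_rejected(self, device):
        with pytest.raises(ValueError):
            weight_of(device.g_max + 1.0, device.g_min, device)


class TestForward:
    def test_zero_weights_give_half_activations_and_tie_break(self, device):
        cfg = AnnConfig(init_scale_input=0.0, init_scale_output=0.0)
        state = init_network(cfg, device, seed=0)
        rng = np.random.default_rng(1)
        h, y = forward(state, _random_pattern(rng))
        np.testing.assert_allclose(h, 0.5)
        np.testing.assert_allclose(y, 0.5)
        assert int(np.argmax(y)) == 0  # ties resolve to the lowest class

    def test_outputs_bounded(self, device):
        cfg = AnnConfig()
        state = init_network(cfg, device, seed=2)
        rng = np.random.default_rng(3)
        for _ in range(1000):
            _, y = forward(state, _random_pattern(rng))
            assert np.all((y > 0) & (y < 1))

    def test_matches_naive_double_loop(self, device):
        """Vectorized forward pass equals an index-by-index re-implementation."""
        cfg = AnnConfig()
        state = init_network(cfg, device, seed=4)
        w1, w2 = state.weights()
        rng = np.random.default_rng(5)
        for _ in range(10):
            xpat = _random_pattern(rng)
            x = 2.0 * xpat - 1.0  # bipolar encoding
            h_naive = np.empty(cfg.n_hidden)
            for j in range(cfg.n_hidden):
                acc = 0.0
                for i in range(cfg.n_input):
                    acc += x[i] * w1[i, j]
                h_naive[j] = 1.0 / (1.0 + np.exp(-acc))
            y_naive = np.empty(cfg.n_output)
            for k in range(cfg.n_output):
                acc = 0.0
                for j in range(cfg.n_hidden):
                    acc += h_naive[j] * w2[j, k]
                y_naive[k] = 1.0 / (1.0 + np.exp(-acc))
            h, y = forward(state, xpat)
            np.testing.assert_allclose(h, h_naive, atol=1e-12)
            np.testing.assert_allclose(y, y_naive, atol=1e-12)

    def test_width_mismatch_rejected(self, device):
        state = init_network(AnnConfig(), device, seed=0)
        with pytest.raises(ValueError):
            forward(state, np.ones(26))


class TestTrainStep:
    def test_correctly_classified_pattern_is_fixed_point(self, device):
        """With zero margin, a pattern whose arg-max already matches the
        target triggers no pulses and leaves the state unchanged."""
        cfg = AnnConfig(update_margin=0.0)
        state = init_network(cfg, device, seed=6)
        rng = np.random.default_rng(7)
        x = _random_pattern(rng)
        _, y = forward(state, x)
        target = int(np.argmax(y))
        before = state.copy()
        train_step(state, x, target, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(state.p1_plus, before.p1_plus)
        np.testing.assert_array_equal(state.p1_minus, before.p1_minus)
        np.testing.assert_array_equal(state.p2_plus, before.p2_plus)
        np.testing.assert_array_equal(state.p2_minus, before.p2_minus)

    def test_update_sign_matches_finite_difference_gradient(self, device):
        """Requested weight changes descend the cross-entropy loss: their
        signs match central finite differences on random instances."""
        cfg = AnnConfig(ideal=True, error_deadzone=0.0, update_margin=0.0)
        rng = np.random.default_rng(8)
        for trial in range(5):
            state = init_network(cfg, device, seed=100 + trial)
            xpat = _random_pattern(rng)
            x = 2.0 * xpat - 1.0
            _, y = forward(state, xpat)
            target_idx = (int(np.argmax(y)) + 1) % cfg.n_output  # force an error
            t = np.zeros(cfg.n_output)
            t[target_idx] = 1.0

            def loss(w1, w2):
                h = _sigmoid(x @ w1)
                yy = _sigmoid(h @ w2)
                return float(-np.sum(t * np.log(yy) + (1 - t) * np.log(1 - yy)))

            dw1, dw2 = backprop_deltas(state, x, t)
            eps = 1e-6
            for arr, dw in ((state.w1, dw1), (state.w2, dw2)):
                idx = tuple(rng.integers(s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                up = loss(state.w1, state.w2)
                arr[idx] = orig - eps
                down = loss(state.w1, state.w2)
                arr[idx] = orig
                grad = (up - down) / (2 * eps)
                if abs(grad) > 1e-9 and abs(dw[idx]) > 0:
                    assert np.sign(dw[idx]) == -np.sign(grad)

    def test_continuous_limit_matches_plain_gradient_descent(self, linear_device):
        """With a near-linear device and unquantized updates, one step
        applies exactly the requested weight deltas."""
        cfg = AnnConfig(quantization="none")
        state = init_network(cfg, linear_device, seed=9)
        rng = np.random.default_rng(10)
        xpat = _random_pattern(rng)
        _, y = forward(state, xpat)
        target = (int(np.argmax(y)) + 1) % cfg.n_output
        t = np.zeros(cfg.n_output)
        t[target] = 1.0
        w1_before, w2_before = state.weights()
        dw1, dw2 = backprop_deltas(state, 2.0 * xpat - 1.0, t)
        train_step(state, xpat, t, rng=np.random.default_rng(0))
        w1_after, w2_after = state.weights()
        np.testing.assert_allclose(w1_after, w1_before + dw1, atol=1e-6)
        np.testing.assert_allclose(w2_after, w2_before + dw2, atol=1e-6)

    def test_conductance_bounds_never_violated(self, device):
        """Thousands of random training steps never push any pair member
        outside [g_min, g_max] nor any weight outside [-1, 1]."""
        cfg = AnnConfig(n_hidden=6, n_output=4)
        state = init_network(cfg, device, seed=11)
        rng = np.random.default_rng(12)
        step_rng = np.random.default_rng(13)
        for _ in range(3000):
            x = _random_pattern(rng)
            target = int(rng.integers(cfg.n_output))
            train_step(state, x, target, rng=step_rng)
        (g1p, g1m), (g2p, g2m) = state.conductances()
        for g in (g1p, g1m, g2p, g2m):
            assert np.all(g >= device.g_min - 1e-9)
            assert np.all(g <= device.g_max + 1e-9)
        w1, w2 = state.weights()
        assert np.all(np.abs(w1) <= 1.0 + 1e-9)
        assert np.all(np.abs(w2) <= 1.0 + 1e-9)


class TestEvaluateAndTrain:
    def test_oracle_state_scores_100(self, device, single_sets):
        """A network engineered to output each pattern's own label scores
        100%: nearest-class-mean templates written into the first layer."""
        train_set, infer_set = single_sets
        cfg = AnnConfig(
            n_hidden=len(train_set.class_names),
            n_output=len(train_set.class_names),
            ideal=True,
        )
        state = init_network(cfg, device, seed=0)
        X = 2.0 * train_set.inputs() - 1.0
        labels = train_set.targets()
        templates = np.stack([X[labels == k].mean(axis=0) for k in range(cfg.n_output)])
        state.w1 = templates.T * 1.0
        state.w2 = (np.eye(cfg.n_output) * 8.0) - 4.0 / cfg.n_output
        assert evaluate(state, train_set) == 100.0

    def test_untrained_accuracy_at_chance_level(self, device, single_sets):
        """Untrained random networks on a balanced 4-class set average the
        25% chance level (200 seeds, within 3 standard errors)."""
        _, infer_set = single_sets
        accs = [
            evaluate(init_network(AnnConfig(), device, seed=s), infer_set)
            for s in range(200)
        ]
        mean, se = np.mean(accs), np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 25.0) < 3 * max(se, 1e-9)

    def test_duplicating_patterns_leaves_accuracy_unchanged(self, device, single_sets):
        _, infer_set = single_sets
        state = init_network(AnnConfig(), device, seed=1)
        doubled = PatternDataset(
            patterns=list(infer_set.patterns) * 2,
            class_names=infer_set.class_names,
            split="inference",
        )
        assert evaluate(state, infer_set) == pytest.approx(evaluate(state, doubled))

    def test_training_is_bit_reproducible(self, device, single_sets):
        train_set, infer_set = single_sets
        cfg = AnnConfig(total_steps=300)
        t1 = train(init_network(cfg, device, seed=2), train_set, infer_set, cfg, seed=2)
        t2 = train(init_network(cfg, device, seed=2), train_set, infer_set, cfg, seed=2)
        np.testing.assert_array_equal(t1.accuracy, t2.accuracy)

    def test_zero_steps_gives_untrained_baseline_only(self, device, single_sets):
        train_set, infer_set = single_sets
        cfg = AnnConfig(total_steps=0, steps_per_epoch=1)
        traj = train(init_network(cfg, device, seed=3), train_set, infer_set, cfg, seed=3)
        assert list(traj.steps) == [0]

    def test_trajectory_values_bounded(self, device, single_sets):
        train_set, infer_set = single_sets
        cfg = AnnConfig(total_steps=500)
        traj = train(init_network(cfg, device, seed=4), train_set, infer_set, cfg, seed=4)
        assert np.all((traj.accuracy >= 0) & (traj.accuracy <= 100))
        assert np.all(np.diff(traj.steps) > 0)

    def test_state_json_round_trip(self, device, single_sets):
        train_set, infer_set = single_sets
        cfg = AnnConfig(total_steps=100)
        state = init_network(cfg, device, seed=5)
        train(state, train_set, infer_set, cfg, seed=5)
        back = state_from_json(state.to_json())
        assert evaluate(back, infer_set) == pytest.approx(
            evaluate(state, infer_set), abs=1e-9
        )


class TestLinearitySweep:
    def test_near_linear_device_beats_strongly_nonlinear(self, single_sets):
        """Qualitative linearity-accuracy link: a near-linear device trains
        to strictly higher accuracy than one with |A| = P_max/20."""
        train_set, infer_set = single_sets
        cfg = AnnConfig(total_steps=300)
        devices = [
            DeviceParams(g_min=100.0, g_max=170.3, p_max=100, a_p=1e6, a_d=1e6),
            DeviceParams(g_min=100.0, g_max=170.3, p_max=100, a_p=5.0, a_d=5.0),
        ]
        table = linearity_sweep(devices, train_set, infer_set, cfg, seeds=range(10))
        assert len(table) == 2
        linear_acc = table.loc[0, "mean_final_accuracy_pct"]
        nonlinear_acc = table.loc[1, "mean_final_accuracy_pct"]
        assert linear_acc > nonlinear_acc

    def test_identical_devices_indistinguishable(self, device, single_sets):
        """Control: the same device twice yields identical paired-seed results."""
        train_set, infer_set = single_sets
        cfg = AnnConfig(total_steps=200)
        table = linearity_sweep([device, device], train_set, infer_set, cfg, seeds=(0, 1))
        assert table.loc[0, "mean_final_accuracy_pct"] == pytest.approx(
            table.loc[1, "mean_final_accuracy_pct"]
        )

    def test_single_device_rejected(self, device, single_sets):
        train_set, infer_set = single_sets
        with pytest.raises(ValueError):
            linearity_sweep([device], train_set, infer_set, AnnConfig())
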