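"""Training tests: deltas, schedules, the full step, loop, and ANN baseline."""

import numpy as np
import pytest

from gsdsnn import training as tr
from gsdsnn.crossbar import SynapseArray
from gsdsnn.data_io import synth_splits
from gsdsnn.device_model import VariationConfig
from gsdsnn.network import NetworkConfig


class TestTargetTrain:
    def test_correct_label_fires_every_step(self):
        t = tr.target_train(3, 10, 20)
        assert t[:, 3].sum() == 20
        assert t.sum() == 20  # nothing outside the correct row

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            tr.target_train(10, 10, 5)


class TestOutputDelta:
    def test_silent_neuron_full_scale(self):
        T = 20
        target = tr.target_train(0, 3, T)
        silent = np.zeros((T, 3), dtype=np.int8)
        delta = tr.output_delta(target, silent, k=1 / T)
        assert delta[0] == pytest.approx(1.0)  # the stated 1 V maximum
        assert np.all(delta[1:] == 0)

    def test_converged_output_zero(self):
        target = tr.target_train(1, 4, 10)
        assert not tr.output_delta(target, target, 0.1).any()

    def test_hand_count_difference(self):
        T, k = 20, 0.05
        target = tr.target_train(0, 2, T)
        out = np.zeros((T, 2), dtype=np.int8)
        out[:8, 0] = 1  # 8 output spikes vs 20 target spikes
        assert tr.output_delta(target, out, k)[0] == pytest.approx(0.6)


class TestBackpropDeltas:
    def test_all_bits_zero_gives_zero_hidden(self, make_array):
        arrays = [make_array(np.ones((3, 2))), make_array(np.ones((2, 2)))]
        deltas = tr.backprop_deltas(arrays, [np.zeros(2), np.ones(2)],
                                    np.array([0.5, -0.5]), tr.TrainConfig())
        assert not deltas[0].any()

    def test_hand_two_layer(self, make_array):
        W2 = np.array([[0.5, -0.2], [0.1, 0.3]])
        arrays = [make_array(np.ones((2, 2))), make_array(W2)]
        delta_L = np.array([0.4, -0.2])
        bits = [np.array([1, 1]), np.array([1, 1])]
        deltas = tr.backprop_deltas(arrays, bits, delta_L, tr.TrainConfig())
        np.testing.assert_allclose(deltas[0], W2 @ delta_L, atol=1e-12)
        np.testing.assert_allclose(deltas[1], delta_L, atol=1e-12)

    def test_clipping_to_full_scale(self, make_array):
        arrays = [make_array(np.ones((2, 2))), make_array(np.full((2, 2), 1.0))]
        cfg = tr.TrainConfig(kappa_bp=100.0, delta_clip=1.0)
        deltas = tr.backprop_deltas(arrays, [np.ones(2), np.ones(2)],
                                    np.array([1.0, 1.0]), cfg)
        assert np.all(np.abs(deltas[0]) <= 1.0)


class TestUpdateSchedule:
    def test_silent_row_gets_no_pulse(self):
        sched = tr.update_schedule(np.array([0, 1]), np.array([0.6, -0.2]), 500e-6)
        assert not sched.delta_t[0].any()
        assert not sched.polarity[0].any()

    def test_width_and_polarity(self):
        sched = tr.update_schedule(np.array([1]), np.array([0.6]), 500e-6)
        assert sched.delta_t[0, 0] == pytest.approx(300e-6)  # 500 us/V * 0.6 V
        assert sched.polarity[0, 0] == 1

    def test_sign_symmetry(self):
        up = tr.update_schedule(np.array([1]), np.array([0.6]), 500e-6)
        down = tr.update_schedule(np.array([1]), np.array([-0.6]), 500e-6)
        assert up.delta_t[0, 0] == down.delta_t[0, 0]
        assert down.polarity[0, 0] == -1


class TestTrainStep:
    def _setup(self, make_array, sizes=(4, 3, 2), T=10):
        cfg = NetworkConfig(sizes, T=T)
        rng = np.random.default_rng(5)
        arrays = [make_array(rng.uniform(-0.3, 0.5, (a, b)))
                  for a, b in zip(sizes[:-1], sizes[1:])]
        return cfg, arrays

    def test_zero_image_no_hidden_updates(self, make_array):
        cfg, arrays = self._setup(make_array)
        before = [a.weights.copy() for a in arrays]
        rng = np.random.default_rng(0)
        scheds, info = tr.train_step(np.zeros(4), 0, arrays, cfg,
                                     tr.TrainConfig(), rng)
        # no spikes anywhere -> S(T)=0 everywhere -> no pulses at all
        for sched, b, a in zip(scheds, before, arrays):
            assert not sched.delta_t.any()
            np.testing.assert_array_equal(a.weights, b)

    def test_deterministic_toy_matches_hand_oracle(self, make_array):
        # intensities in {0,1} make the whole step deterministic
        T = 4
        cfg = NetworkConfig((2, 2, 2), T=T, q_scale=(0.25, 0.25))
        W1 = np.array([[0.6, 0.0], [0.0, 0.2]])
        W2 = np.array([[0.5, -0.4], [0.3, 0.1]])
        arrays = [make_array(W1), make_array(W2)]
        image = np.array([1.0, 0.0])
        rng = np.random.default_rng(0)
        scheds, info = tr.train_step(image, 0, arrays, cfg, tr.TrainConfig(),
                                     rng, apply_updates=False)
        # hand forward: input 0 spikes each step; h0 charge 0.25*0.6=0.15>0.1
        # -> h0 spikes every step; h1 never driven.
        # output charges per step: o0 = 0.25*0.5=0.125 -> spikes each step,
        # o1 = 0.25*(-0.4) < 0 -> silent.
        k = 1 / T
        delta_L = k * np.array([T - T, 0 - 0 * T])  # o0 matches target, o1 silent
        assert np.all(info["deltas"][1] == delta_L)
        # hidden delta: W2 @ delta_L gated by h bits [1, 0] -> all zero here
        np.testing.assert_allclose(info["deltas"][0], [0.0, 0.0], atol=1e-12)
        # schedules: all deltas zero -> no pulses
        assert not scheds[0].delta_t.any()
        assert not scheds[1].delta_t.any()

    def test_case1_mean_approaches_case2_input_layer(self, make_array):
        # frozen network, repeated Poisson presentations of one image:
        # E[S_i(T)] = intensity_i for the input layer, so the mean Case-1 sum
        # converges to the Case-2 value
        cfg, arrays = self._setup(make_array, sizes=(6, 4, 2), T=20)
        rng = np.random.default_rng(11)
        image = rng.uniform(0.1, 0.9, 6)
        c1, c2 = [], []
        for _ in range(600):
            _, info = tr.train_step(image, 1, arrays, cfg, tr.TrainConfig(),
                                    rng, apply_updates=False)
            c1.append(info["case1"][0])
            c2.append(info["case2"][0])
        diff = np.array(c1) - np.array(c2)
        ci = 2.576 * diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < ci

    def test_gating_invariant(self, make_array, rng):
        # weights whose pre-synaptic neuron stayed silent at T never move
        cfg, arrays = self._setup(make_array, sizes=(5, 4, 3), T=8)
        image = rng.uniform(0, 1, 5)
        before = [a.weights.copy() for a in arrays]
        scheds, info = tr.train_step(image, 2, arrays, cfg, tr.TrainConfig(), rng)
        for l, sched in enumerate(scheds):
            silent = ~sched.delta_t.any(axis=1)
            after = arrays[l].weights
            np.testing.assert_array_equal(after[silent], before[l][silent])


class TestTrainLoop:
    def test_zero_epochs_leaves_arrays_unchanged(self, make_array):
        train_ds, test_ds = synth_splits(train_per_class=2, test_per_class=1, seed=0)
        cfg = NetworkConfig((64, 4, 3), T=5)
        arrays = [make_array(np.zeros((64, 4))), make_array(np.zeros((4, 3)))]
        before = [a.weights.copy() for a in arrays]
        trace = tr.train(train_ds, test_ds, arrays, cfg, tr.TrainConfig(epochs=0))
        for a, b in zip(arrays, before):
            np.testing.assert_array_equal(a.weights, b)
        assert trace.epoch_accuracy == []

    def test_lr_schedule_applied_exactly(self, make_array):
        train_ds, test_ds = synth_splits(train_per_class=2, test_per_class=1, seed=0)
        cfg = NetworkConfig((64, 4, 3), T=3)
        arrays = [make_array(np.zeros((64, 4))), make_array(np.zeros((4, 3)))]
        tc = tr.TrainConfig(epochs=3, lr_schedule=((2, 0.2),))
        trace = tr.train(train_ds, test_ds, arrays, cfg, tc)
        assert trace.lambda_history == [1.0, 0.2, 0.2]

    def test_empty_dataset_rejected(self, make_array):
        from gsdsnn.data_io import Dataset
        empty = Dataset(np.zeros((0, 4)), np.zeros(0), 2, (2, 2))
        cfg = NetworkConfig((4, 2), T=3)
        with pytest.raises(ValueError):
            tr.train(empty, empty, [make_array(np.zeros((4, 2)))], cfg,
                     tr.TrainConfig(epochs=1))

    def test_batch_mode_averages_widths(self, make_array, rng):
        # two presentations of opposite-delta stimuli largely cancel in a
        # batch of 2; batch updates must be smaller than per-sample updates
        train_ds, test_ds = synth_splits(train_per_class=4, test_per_class=2, seed=3)
        cfg = NetworkConfig((64, 6, 3), T=10)

        init = np.random.default_rng(1)
        W1 = init.uniform(-0.05, 0.15, (64, 6))
        W2 = init.uniform(-0.2, 0.3, (6, 3))

        def run(batch_size, seed=7):
            arrays = [make_array(W1, seed=1), make_array(W2, seed=2)]
            tc = tr.TrainConfig(epochs=1, batch_size=batch_size, seed=seed)
            tr.train(train_ds, test_ds, arrays, cfg, tc,
                     rng=np.random.default_rng(seed))
            return arrays

        dw_b1 = np.abs(run(1)[0].weights - W1).sum()
        dw_b12 = np.abs(run(12)[0].weights - W1).sum()
        assert dw_b12 < dw_b1

    def test_trace_frame_shape(self, make_array):
        train_ds, test_ds = synth_splits(train_per_class=2, test_per_class=1, seed=0)
        cfg = NetworkConfig((64, 4, 3), T=3)
        arrays = [make_array(np.zeros((64, 4))), make_array(np.zeros((4, 3)))]
        trace = tr.train(train_ds, test_ds, arrays, cfg, tr.TrainConfig(epochs=2))
        df = trace.to_frame()
        assert set(df.columns) == {"iteration", "layer", "case1_sum", "case2_sum"}
        assert len(df) == 2 * 12  # 2 layers x (2 epochs x 6 samples)


class TestReferenceANN:
    def test_separable_toy_perfect(self, rng):
        # direction-separable classes (bias-free nets are scale-invariant)
        proto = np.array([[0.8, 0.8, 0.1, 0.1], [0.1, 0.1, 0.8, 0.8]])
        y = np.repeat([0, 1], 30)
        X = proto[y] + rng.normal(0, 0.03, (60, 4))
        from gsdsnn.data_io import Dataset
        ds = Dataset(np.clip(X, 0, 1), y, 2, (2, 2))
        model = tr.reference_ann(ds, (4, 6, 2), epochs=60, rng=np.random.default_rng(0))
        assert np.mean(model.predict(ds.images) == y) == 1.0

    def test_analytic_gradient_matches_finite_difference(self, rng):
        model = tr.ReLUMLP((5, 4, 3), rng=np.random.default_rng(1))
        X = rng.uniform(0, 1, (7, 5))
        Y = np.eye(3)[rng.integers(0, 3, 7)]
        grads = model.gradients(X, Y)
        eps = 1e-6
        for l in range(2):
            num = np.zeros_like(model.weights[l])
            for idx in np.ndindex(*num.shape):
                model.weights[l][idx] += eps
                up = model.loss(X, Y)
                model.weights[l][idx] -= 2 * eps
                down = model.loss(X, Y)
                model.weights[l][idx] += eps
                num[idx] = (up - down) / (2 * eps)
            np.testing.assert_allclose(grads[l], num, atol=1e-5)

    def test_seeded_fit_reproducible(self, rng):
        train_ds, _ = synth_splits(train_per_class=5, test_per_class=2, seed=0)
        runs = [tr.reference_ann(train_ds, (64, 4, 3), epochs=2,
                                 rng=np.random.default_rng(42)).weights
                for _ in range(2)]
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)


class TestOffchipTransfer:
    def _arrays(self, shapes, params, variation=None, seed=0):
        var = variation or VariationConfig()
        rng = np.random.default_rng(seed)
        return [SynapseArray.create(a, b, params, var, rng, init="floor")
                for a, b in shapes]

    def test_exact_transfer_proportional(self, linear_device, rng):
        W = [rng.uniform(-2, 2, (6, 4)), rng.uniform(-3, 3, (4, 2))]
        arrays = self._arrays([(6, 4), (4, 2)], linear_device)
        tr.offchip_transfer(W, arrays)
        w_max = max(np.abs(w).max() for w in W)
        for w, arr in zip(W, arrays):
            np.testing.assert_allclose(arr.weights, w / w_max, atol=1e-9)

    def test_p2p_variation_applied_once(self, linear_device, rng):
        n = 100
        W = [rng.uniform(0.2, 1.0, (n, n))]
        var = VariationConfig(sigma_p2p=0.1)
        arrays = self._arrays([(n, n)], linear_device, var)
        tr.offchip_transfer(W, arrays, var, np.random.default_rng(8))
        target = W[0] / W[0].max()
        mid = target < 0.7  # away from the clamp at g_max
        rel_err = arrays[0].g_plus.g[mid] / target[mid] - 1
        assert rel_err.std() == pytest.approx(0.1, rel=0.1)

    def test_stuck_devices_stay_off(self, linear_device):
        var = VariationConfig(stuck_fraction=0.2)
        arrays = self._arrays([(10, 10)], linear_device, var, seed=4)
        tr.offchip_transfer([np.full((10, 10), 1.0)], arrays, var)
        stuck = arrays[0].g_plus.stuck
        assert stuck.sum() == 20
        assert np.all(arrays[0].g_plus.g[stuck] == linear_device.g_min)

    def test_all_zero_weights_rejected(self, linear_device):
        arrays = self._arrays([(2, 2)], linear_device)
        with pytest.raises(ValueError):
            tr.offchip_transfer([np.zeros((2, 2))], arrays)
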