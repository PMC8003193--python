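"""Shallow network: forward pass, Jacobian, LM training, persistence."""

import numpy as np
import pytest

from edgesharp import (ProfileDataset, ShallowNet, TrainConfig, forward,
                       init_net, jacobian, load_net, predict_positions,
                       save_net, train_lm)


def _net_like(L, n_h, b_o=0.0, scale=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return ShallowNet(scale * rng.normal(size=(n_h, L)),
                      scale * rng.normal(size=n_h),
                      scale * rng.normal(size=n_h), b_o)


def _dataset(features, targets, rng):
    n = len(features)
    labels = np.array(["train"] * int(0.7 * n) + ["val"] * int(0.25 * n))
    labels = np.concatenate([labels, ["test"] * (n - len(labels))])
    return ProfileDataset(
        features=features,
        targets=targets,
        start_frac=np.full(n, 0.5),
        split=labels[rng.permutation(n)],
        origins=np.zeros((n, 3)),
    )


class TestForward:
    def test_zero_weights_output_bias(self, rng):
        net = _net_like(12, 4, b_o=0.7)
        y = forward(net, rng.uniform(0, 1, (9, 12)))
        assert np.allclose(y, 0.7)

    def test_sigmoid_saturation(self):
        # one hidden unit driven far positive: output -> w_o + b_o
        net = ShallowNet(np.full((1, 5), 100.0), [0.0], [2.5], 0.3)
        y = forward(net, np.full((1, 5), 1.0))
        assert y[0] == pytest.approx(2.8, abs=1e-9)

    def test_matches_scalar_loop(self, rng):
        net = init_net(7, 3, seed=4)
        X = rng.uniform(0, 1, (6, 7))
        y = forward(net, X)
        for i in range(6):
            acc = net.b_o
            for j in range(3):
                z = float(net.w_h[j] @ X[i] + net.b_h[j])
                acc += net.w_o[j] / (1.0 + np.exp(-z))
            assert y[i] == pytest.approx(acc, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            forward(init_net(10, 3), rng.uniform(size=(4, 9)))


class TestJacobian:
    @pytest.mark.parametrize("L,n_h", [(5, 2), (7, 3), (12, 6)])
    def test_matches_central_differences(self, L, n_h, rng):
        net = init_net(L, n_h, seed=L)
        X = rng.uniform(0, 1, (8, L))
        J = jacobian(net, X)
        p0 = net.pack()
        eps = 1e-6
        for k in range(net.n_params):
            p = p0.copy()
            p[k] += eps
            net.unpack(p)
            yp = forward(net, X)
            p[k] -= 2 * eps
            net.unpack(p)
            ym = forward(net, X)
            net.unpack(p0)
            num = (yp - ym) / (2 * eps)
            rel = np.abs(J[:, k] - num) / (np.abs(num) + 1e-8)
            assert rel.max() < 1e-5

    def test_output_bias_column_is_ones(self, rng):
        net = init_net(6, 3, seed=1)
        J = jacobian(net, rng.uniform(0, 1, (5, 6)))
        assert np.allclose(J[:, -1], 1.0)

    def test_zero_input_rows_touch_only_bias_paths(self):
        net = init_net(6, 3, seed=2)
        J = jacobian(net, np.zeros((2, 6)))
        k = 3 * 6
        assert np.allclose(J[:, :k], 0.0)  # dy/dw_h vanishes for zero input
        assert not np.allclose(J[:, k:], 0.0)


class TestTrainLM:
    def test_fits_constant_target_fast(self, rng):
        X = rng.uniform(0, 1, (80, 10))
        ds = _dataset(X, np.full(80, 0.5), rng)
        net, rep = train_lm(ds, TrainConfig(max_epochs=10, seed=0))
        assert min(rep.train_mse) < 1e-6

    def test_accepted_steps_never_increase_training_mse(self, rng):
        X = rng.uniform(0, 1, (120, 8))
        t = X[:, :4].mean(axis=1)
        ds = _dataset(X, t, rng)
        _, rep = train_lm(ds, TrainConfig(max_epochs=40, n_hidden=4, seed=1))
        assert (np.diff(rep.train_mse) < 0).all()

    def test_best_epoch_minimizes_validation_mse(self, rng):
        X = rng.uniform(0, 1, (120, 8))
        ds = _dataset(X, X[:, 0] * 0.5 + 0.2, rng)
        _, rep = train_lm(ds, TrainConfig(max_epochs=30, n_hidden=3, seed=2))
        assert rep.best_epoch == int(np.argmin(rep.val_mse)) + 1
        assert rep.stop_epoch <= 30

    def test_seeded_training_is_deterministic(self, rng):
        X = rng.uniform(0, 1, (90, 6))
        ds = _dataset(X, X[:, 1], rng)
        cfg = TrainConfig(max_epochs=15, n_hidden=3, seed=7)
        net_a, rep_a = train_lm(ds, cfg)
        net_b, rep_b = train_lm(ds, cfg)
        assert rep_a.train_mse == rep_b.train_mse
        assert np.array_equal(net_a.pack(), net_b.pack())

    def test_empty_split_rejected(self, rng):
        X = rng.uniform(0, 1, (20, 5))
        ds = _dataset(X, X[:, 0], rng)
        ds.split[ds.split == "test"] = "train"
        with pytest.raises(ValueError, match="test"):
            train_lm(ds, TrainConfig())


class TestPredictPositions:
    def _constant_output_dataset(self, rng, n=4, L=100):
        ds = _dataset(rng.uniform(0, 1, (n, L)), np.full(n, 0.5), rng)
        ds.origins = np.column_stack([np.full(n, 150.0), np.full(n, 150.0),
                                      np.zeros(n)])
        return ds

    def test_fraction_030_maps_to_position_30(self, rng):
        ds = self._constant_output_dataset(rng)
        net = _net_like(100, 2, b_o=0.3)
        pred = predict_positions(net, ds)
        assert np.allclose(pred.positions_px, 30.0)
        # 20 px inside the centered origin, along theta = 0
        assert np.allclose(pred.points_xy[:, 0], 130.0)

    def test_fraction_half_is_midpoint_for_any_length(self, rng):
        for L in (10, 40, 100):
            ds = self._constant_output_dataset(rng, L=L)
            net = _net_like(L, 2, b_o=0.5)
            pred = predict_positions(net, ds)
            assert np.allclose(pred.positions_px, L / 2)
            assert np.allclose(pred.points_xy, ds.origins[:, :2])

    def test_clip_option_bounds_outputs(self, rng):
        ds = self._constant_output_dataset(rng)
        net = _net_like(100, 2, b_o=-0.07)
        clipped = predict_positions(net, ds, clip=True)
        assert np.allclose(clipped.positions_px, 0.0)
        assert clipped.n_clipped == len(ds)
        raw = predict_positions(net, ds)
        assert np.allclose(raw.positions_px, -7.0)  # extrapolation preserved


class TestPersistence:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        net = init_net(10, 4, seed=3)
        path = tmp_path / "net.json"
        save_net(net, path)
        loaded = load_net(path)
        assert np.array_equal(loaded.pack(), net.pack())
        X = rng.uniform(0, 1, (5, 10))
        assert np.array_equal(forward(loaded, X), forward(net, X))

    def test_tampered_shape_rejected(self, tmp_path):
        import json

        net = init_net(6, 2, seed=0)
        path = tmp_path / "net.json"
        save_net(net, path)
        payload = json.loads(path.read_text())
        payload["n_hidden"] = 5
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="shapes"):
            load_net(path)

    def test_parameter_count_for_reference_architecture(self):
        # N_H*L + N_H + N_H + 1 with L=100, N_H=20
        assert init_net(100, 20).n_params == 20 * 100 + 20 + 20 + 1 == 2041
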