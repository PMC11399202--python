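import numpy as np
import pytest

from hardigen._nnops import Conv1, Conv3, ConvT3
from hardigen.dwi_io import DWIVolume
from hardigen.unet3d import (
    ModelConfig,
    TrainConfig,
    assemble_arms,
    build_model,
    load_model,
    predict,
    predict_volume,
    save_model,
    train,
)

TINY = ModelConfig(input_channels=3, output_channels=2, levels=2, base_filters=4, seed=0)


def closed_form_parameter_count(cfg: ModelConfig) -> int:
    """Independent layer-by-layer count: conv k^3 has k^3*Cin*Cout + Cout
    parameters, the 1x1x1 head has Cin*Cout + Cout."""
    k3 = cfg.kernel_size**3
    f, L = cfg.base_filters, cfg.levels
    total = 0
    cin = cfg.input_channels
    for i in range(L):
        ch = f * 2**i
        total += k3 * cin * ch + ch  # same-resolution encoder conv
        if i < L - 1:
            nxt = f * 2 ** (i + 1)
            total += k3 * ch * nxt + nxt  # stride-2 downsampling conv
            cin = nxt
    for i in range(L - 2, -1, -1):
        ch = f * 2**i
        total += k3 * (f * 2 ** (i + 1)) * ch + ch  # transposed conv
        total += k3 * (2 * ch) * ch + ch  # post-concat decoder conv
    head_in = f + (cfg.input_channels if cfg.input_skip else 0)
    total += head_in * cfg.output_channels + cfg.output_channels
    return total


class TestArchitecture:
    @pytest.mark.parametrize(
        "cfg",
        [
            ModelConfig(levels=3, base_filters=16),
            ModelConfig(levels=2, base_filters=8),
            ModelConfig(levels=1, base_filters=4),
            ModelConfig(levels=2, base_filters=4, input_skip=False),
            TINY,
        ],
    )
    def test_parameter_count_matches_closed_form(self, cfg):
        assert build_model(cfg).n_parameters == closed_form_parameter_count(cfg)

    def test_output_shape_matches_input(self, rng):
        m = build_model(TINY)
        x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
        y = m.forward(x)
        assert y.shape == (2, 8, 8, 8)

    def test_default_output_channel_count_is_32(self):
        assert ModelConfig().output_channels == 32

    def test_indivisible_shape_names_axis(self, rng):
        m = build_model(ModelConfig(input_channels=3, output_channels=2, levels=3, base_filters=4))
        x = rng.normal(size=(3, 8, 8, 6)).astype(np.float32)
        with pytest.raises(ValueError, match="axis 2"):
            m.forward(x)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_size=4)

    @pytest.mark.parametrize(
        "layer_factory,cin,spatial",
        [
            (lambda rng: Conv3(3, 4, 3, 1, rng), 3, (4, 4, 4)),
            (lambda rng: Conv3(3, 4, 3, 2, rng), 3, (4, 4, 4)),
            (lambda rng: ConvT3(3, 4, 3, 2, rng), 3, (2, 2, 2)),
            (lambda rng: Conv1(3, 4, rng), 3, (4, 4, 4)),
        ],
        ids=["conv_s1", "conv_s2", "convT_s2", "conv1x1"],
    )
    def test_primitive_gradients_match_finite_differences(self, rng, layer_factory, cin, spatial):
        """Each conv primitive is linear, so central differences are exact
        up to float32 rounding for both weight and input gradients."""
        layer = layer_factory(rng)
        x = rng.normal(size=(cin,) + spatial).astype(np.float32)
        y = layer.forward(x)
        R = rng.normal(size=y.shape).astype(np.float32)
        for _, g in layer.params():
            g[...] = 0.0
        dx = layer.backward(R)

        def loss():
            return float(np.sum(layer.forward(x).astype(np.float64) * R))

        for P, G in layer.params():
            flat, gflat = P.ravel(), G.ravel()
            for i in np.linspace(0, flat.size - 1, 5).astype(int):
                eps, old = 1e-2, flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                if abs(num) > 1e-4:
                    assert gflat[i] == pytest.approx(num, rel=1e-2)
        xf, dxf = x.ravel(), dx.ravel()
        for i in np.linspace(0, xf.size - 1, 6).astype(int):
            eps, old = 1e-2, xf[i]
            xf[i] = old + eps
            lp = loss()
            xf[i] = old - eps
            lm = loss()
            xf[i] = old
            num = (lp - lm) / (2 * eps)
            if abs(num) > 1e-4:
                assert dxf[i] == pytest.approx(num, rel=1e-2)

    def test_network_gradients_match_finite_differences(self, rng, monkeypatch):
        """Wiring oracle: with the activation replaced by identity the whole
        network is linear, so its backward pass must match central
        differences exactly (the kink-free setting isolates the skip and
        concat plumbing from ReLU's nondifferentiability)."""
        import hardigen.unet3d as U

        monkeypatch.setattr(U, "relu", lambda x: x)
        monkeypatch.setattr(U, "relu_grad", lambda dy, y: dy)
        m = build_model(ModelConfig(input_channels=2, output_channels=2, levels=3, base_filters=2))
        x = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        R = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)

        def loss():
            return float(np.sum(m.forward(x).astype(np.float64) * R))

        m.zero_grad()
        m.forward(x)
        m.backward(R)
        for layer in m._layers():
            for P, G in layer.params():
                flat, gflat = P.ravel(), G.ravel()
                for i in np.linspace(0, flat.size - 1, 4).astype(int):
                    # the identity-activation net is linear in each weight's
                    # neighborhood, so a generous step just averages out
                    # float32 rounding in the loss
                    eps, old = 1e-1, flat[i]
                    flat[i] = old + eps
                    lp = loss()
                    flat[i] = old - eps
                    lm = loss()
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    if abs(num) > 1e-3:
                        assert gflat[i] == pytest.approx(num, rel=2e-2)


def toy_pairs(rng, n, channels=(3, 2), size=8):
    out = []
    for _ in range(n):
        x = rng.uniform(0, 1, size=(channels[0], size, size, size)).astype(np.float32)
        y = (x[: channels[1]] * 0.8 + 0.1).astype(np.float32)
        out.append((x, y))
    return out


class TestTraining:
    def test_loss_decreases_on_toy_data(self, rng):
        pairs = toy_pairs(rng, 2)
        m = build_model(TINY)
        state = train(m, pairs, [], TrainConfig(minibatch_size=2, epochs=5, learning_rate=3e-3))
        assert state.train_mse[-1] < state.train_mse[0]
        assert len(state.train_mse) == len(state.val_mse) == 5
        assert all(v >= 0 for v in state.train_mse)

    def test_zero_targets_monotone_descent(self, rng):
        pairs = [(x, np.zeros_like(y)) for x, y in toy_pairs(rng, 2)]
        m = build_model(TINY)
        state = train(m, pairs, [], TrainConfig(minibatch_size=2, epochs=5, learning_rate=1e-3))
        assert all(b < a for a, b in zip(state.train_mse, state.train_mse[1:]))

    def test_same_seed_reproduces_loss_curves(self, rng):
        pairs = toy_pairs(rng, 3)
        cfg = TrainConfig(minibatch_size=2, epochs=3, learning_rate=1e-3, seed=5)
        s1 = train(build_model(TINY), pairs, pairs[:1], cfg)
        s2 = train(build_model(TINY), pairs, pairs[:1], cfg)
        assert s1.train_mse == s2.train_mse
        assert s1.val_mse == s2.val_mse

    def test_shape_mismatch_rejected(self, rng):
        x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
        y = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        with pytest.raises(ValueError):
            train(build_model(TINY), [(x, y)], [], TrainConfig(epochs=1))

    def test_divergence_reports_epoch(self, rng):
        pairs = toy_pairs(rng, 1)
        m = build_model(TINY)
        bad = TrainConfig(minibatch_size=1, epochs=3, learning_rate=1e-3)
        m.out.W[...] = np.nan
        from hardigen.unet3d import TrainingDivergedError

        with pytest.raises(TrainingDivergedError) as err:
            train(m, pairs, [], bad)
        assert err.value.epoch == 1

    def test_best_epoch_checkpoint_restored(self, rng):
        pairs = toy_pairs(rng, 2)
        m = build_model(TINY)
        state = train(m, pairs, pairs, TrainConfig(minibatch_size=2, epochs=6, learning_rate=3e-3))
        restored_val = float(np.mean([np.mean((m.forward(x) - y) ** 2) for x, y in pairs]))
        assert restored_val == pytest.approx(min(state.val_mse), rel=1e-5)

    def test_memorizes_single_phantom(self, scheme64, split64):
        """Capacity sanity: on a one-phantom dataset the compact network
        drives the training MSE down by >= 100x within 150 epochs."""
        import numpy as np

        from hardigen.dwi_io import apply_normalization
        from hardigen.phantom import PhantomConfig, generate_dataset

        first, second = split64
        ds = generate_dataset(
            scheme64, PhantomConfig(n_train=1, n_val=0, n_test=0), seed=5
        )
        pos = {lab: i for i, lab in enumerate(scheme64.labels)}
        vol = apply_normalization(ds["train"][0].volume)
        data = np.moveaxis(vol.data, -1, 0)
        pair = [
            (data[[pos[l] for l in first.labels]], data[[pos[l] for l in second.labels]])
        ]
        m = build_model(ModelConfig(levels=3, base_filters=8, seed=0))
        state = train(
            m, pair, [], TrainConfig(minibatch_size=1, epochs=150, learning_rate=3e-3)
        )
        assert state.train_mse[0] / min(state.train_mse) >= 100.0

    def test_cosine_schedule_endpoints(self):
        cfg = TrainConfig(epochs=10, learning_rate=1e-2, lr_schedule="cosine")
        assert cfg.lr_at(0) == pytest.approx(1e-2)
        assert cfg.lr_at(9) == pytest.approx(1e-2 * cfg.lr_final_fraction)


class TestPrediction:
    def test_deterministic_and_clamped(self, rng):
        m = build_model(TINY)
        x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
        y1, y2 = predict(m, x), predict(m, x)
        assert np.array_equal(y1, y2)
        assert y1.min() >= 0.0

    def test_volume_wrapper_carries_scheme_and_affine(self, rng, scheme64, split64):
        first, second = split64
        cfg = ModelConfig(input_channels=33, output_channels=32, levels=2, base_filters=4)
        m = build_model(cfg)
        data = rng.uniform(0, 1, size=(8, 8, 8, 33)).astype(np.float32)
        vol = DWIVolume(data, np.diag([2.5, 2.5, 2.5, 1.0]), first, {"scale": 1.0})
        out = predict_volume(m, vol, second)
        assert out.data.shape == (8, 8, 8, 32)
        assert np.array_equal(out.affine, vol.affine)
        assert out.scheme is second

    def test_channel_mismatch_rejected(self, rng, scheme64, split64):
        first, second = split64
        m = build_model(TINY)
        data = rng.uniform(0, 1, size=(8, 8, 8, 33)).astype(np.float32)
        vol = DWIVolume(data, np.eye(4), first)
        with pytest.raises(ValueError, match="channels"):
            predict_volume(m, vol, second)


class TestArms:
    def make_volumes(self, rng, scheme64, split64):
        first, second = split64
        aff = np.eye(4)
        inp = DWIVolume(rng.uniform(0, 1, (4, 4, 4, 33)).astype(np.float32), aff, first)
        pred = DWIVolume(rng.uniform(0, 1, (4, 4, 4, 32)).astype(np.float32), aff, second)
        ref = DWIVolume(rng.uniform(0, 1, (4, 4, 4, 32)).astype(np.float32), aff, second)
        return inp, pred, ref

    def test_channel_counts(self, rng, scheme64, split64):
        arms = assemble_arms(*self.make_volumes(rng, scheme64, split64))
        assert arms["a"].data.shape[-1] == 33
        assert arms["b"].data.shape[-1] == 65
        assert arms["c"].data.shape[-1] == 65

    def test_arm_b_prefix_identical_to_arm_a(self, rng, scheme64, split64):
        arms = assemble_arms(*self.make_volumes(rng, scheme64, split64))
        assert np.array_equal(arms["b"].data[..., :33], arms["a"].data)

    def test_arm_schemes_consistent(self, rng, scheme64, split64):
        arms = assemble_arms(*self.make_volumes(rng, scheme64, split64))
        assert len(arms["b"].scheme) == 65
        assert np.allclose(
            arms["b"].scheme.directions, arms["c"].scheme.directions
        )

    def test_grid_mismatch_rejected(self, rng, scheme64, split64):
        inp, pred, ref = self.make_volumes(rng, scheme64, split64)
        small = DWIVolume(pred.data[:2], pred.affine, pred.scheme)
        with pytest.raises(ValueError):
            assemble_arms(inp, small, ref)


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        m = build_model(TINY)
        x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
        save_model(m, tmp_path / "model.npz")
        back = load_model(tmp_path / "model.npz")
        assert back.config == m.config
        assert np.array_equal(predict(back, x), predict(m, x))
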