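import numpy as np
import pytest

from pwqus import nn
from pwqus.qusnet import (
    ConditionalQUSNet,
    condition_index,
    condition_onehot,
    loss_qi,
    split_dataset,
)


class TestConditionalInstanceNorm:
    def test_identity_on_standardized_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (2, 3, 16, 16))
        x = (x - x.mean(axis=(2, 3), keepdims=True)) / x.std(axis=(2, 3), keepdims=True)
        cin = nn.ConditionalInstanceNorm(3, eps=0.0)
        out = cin.forward(x, np.array([0, 1]))
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_zero_gamma_collapses_to_beta(self):
        cin = nn.ConditionalInstanceNorm(2)
        cin.gamma[:] = 0.0
        cin.beta[1] = [3.0, -1.0]
        x = np.random.default_rng(1).normal(0, 2, (1, 2, 8, 8))
        out = cin.forward(x, np.array([1]))
        np.testing.assert_allclose(out[0, 0], 3.0)
        np.testing.assert_allclose(out[0, 1], -1.0)

    def test_hand_computed_example(self):
        # x = [1 2 3 4], gamma = 2, beta = 1, population sigma, eps = 0
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 2, 2)
        cin = nn.ConditionalInstanceNorm(1, eps=0.0)
        cin.gamma[0] = 2.0
        cin.beta[0] = 1.0
        out = cin.forward(x, np.array([0])).ravel()
        np.testing.assert_allclose(
            out, [-1.6833, 0.1056, 1.8944, 3.6833], atol=1e-4
        )


class TestConditionVector:
    def test_name_index_onehot_agree(self):
        assert condition_index("AC") == 0
        assert condition_index("ESC") == 3
        np.testing.assert_array_equal(condition_onehot("SoS"), [0, 1, 0, 0])
        assert condition_index(condition_onehot("ESD")) == 2

    @pytest.mark.parametrize("bad", [[1, 1, 0, 0], [0, 0, 0, 0], [2, 0, 0, 0]])
    def test_malformed_onehot_rejected(self, bad):
        with pytest.raises(ValueError):
            condition_index(np.array(bad))


@pytest.fixture(scope="module")
def tiny_net():
    net = ConditionalQUSNet(
        stage_channels=(3, 4, 6),
        branch_channels=(6, 4, 3, 2),
        input_channels=2,
        seed=7,
    )
    net._build()
    return net


class TestEncoderDecoder:
    def test_latent_is_16_by_16(self, tiny_net):
        X = np.random.default_rng(0).normal(0, 1, (2, 2, 128, 128)).astype(np.float32)
        q = tiny_net.encode(X, cond=["AC", "SoS"])
        assert q.shape == (2, 6, 16, 16)

    def test_condition_switch_changes_latent(self, tiny_net):
        # CIN tables are initialized identically, so nudge one condition
        tiny_net.encoder_[0]["norm"].gamma[1] += 0.3
        X = np.random.default_rng(1).normal(0, 1, (1, 2, 128, 128)).astype(np.float32)
        q0 = tiny_net.encode(X, cond=["AC"])
        q1 = tiny_net.encode(X, cond=["SoS"])
        assert not np.allclose(q0, q1)

    def test_incompatible_input_size_raises(self, tiny_net):
        X = np.zeros((1, 2, 64, 64), dtype=np.float32)
        with pytest.raises(ValueError, match="16 x 16"):
            tiny_net.encode(X, cond=["AC"])

    def test_auxiliary_resolutions_exactly_16_32_64_128(self, tiny_net):
        X = np.random.default_rng(2).normal(0, 1, (2, 2, 128, 128)).astype(np.float32)
        final, aux = tiny_net.forward_full(X, cond=["AC", "ESD"])
        assert final.shape == (2, 128, 128)
        assert sorted(aux) == [16, 32, 64, 128]
        for r, arr in aux.items():
            assert arr.shape == (2, r, r)

    def test_residual_block_is_identity_at_init(self, tiny_net):
        # the second conv of each residual block starts at zero
        for br in tiny_net.branches_:
            assert np.all(br["conv2"].w == 0.0)
        q = np.random.default_rng(3).normal(0, 1, (1, 6, 16, 16)).astype(np.float32)
        br = tiny_net.branches_[1]
        u = nn.upsample_nearest(br["proj"].forward(q), br["factor"])
        res = u + br["conv2"].forward(br["relu1"].forward(br["conv1"].forward(u)))
        np.testing.assert_allclose(res, u)

    def test_gradient_reaches_every_subnetwork(self, tiny_net):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (2, 2, 128, 128)).astype(np.float32)
        y = rng.uniform(0, 1, (2, 128, 128)).astype(np.float32)
        tiny_net._zero_grads()
        final, aux = tiny_net._forward(X, np.array([0, 1]))
        aux_t = {r: nn.avg_pool(y[:, None], 128 // r)[:, 0] for r in tiny_net.RESOLUTIONS}
        dfinal = 2 * (final - y) / 2
        daux = {r: 2 * (aux[r] - aux_t[r]) / 2 for r in tiny_net.RESOLUTIONS}
        tiny_net._backward(dfinal, daux)
        for br in tiny_net.branches_:
            assert np.linalg.norm(br["head"].grads["w"]) > 0
            assert np.linalg.norm(br["conv2"].grads["w"]) > 0


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        y = np.random.default_rng(0).uniform(0, 1, (3, 128, 128))
        aux = {r: nn.avg_pool(y[:, None], 128 // r)[:, 0] for r in (16, 32, 64, 128)}
        total, parts = loss_qi(y, aux, y, aux, 0.0, [])
        assert total == 0.0

    def test_constant_offset_gives_c_squared_times_n(self):
        # single resolution, prediction off by c on every pixel (sum convention)
        c = 0.37
        y = np.zeros((1, 16, 16))
        pred = y + c
        total, parts = loss_qi(pred, {16: y[:, :16, :16] + c}, y, {16: y}, 0.0, [])
        assert parts["main"] == pytest.approx(c**2 * 16 * 16)

    def test_l2_strictly_increases_loss(self):
        y = np.random.default_rng(1).uniform(0, 1, (2, 16, 16))
        w = [np.ones((4, 9))]
        base, _ = loss_qi(y, {}, y, {}, 0.0, w)
        reg, parts = loss_qi(y, {}, y, {}, 1e-4, w)
        assert reg > base
        assert parts["L2"] == pytest.approx(1e-4 * 36)

    def test_decomposition_is_exact(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 1, (2, 128, 128))
        pred = rng.uniform(0, 1, (2, 128, 128))
        aux = {r: rng.uniform(0, 1, (2, r, r)) for r in (16, 32, 64, 128)}
        aux_t = {r: nn.avg_pool(y[:, None], 128 // r)[:, 0] for r in (16, 32, 64, 128)}
        w = [rng.normal(0, 1, (3, 3))]
        total, parts = loss_qi(pred, aux, y, aux_t, 1e-3, w)
        assert total == pytest.approx(parts["main"] + parts["L_R"] + parts["L2"])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            loss_qi(np.zeros((1, 8, 8)), {}, np.zeros((1, 4, 4)), {}, 0, [])


class TestSplit:
    def test_study_ratio(self):
        tr, te = split_dataset(16500, seed=0)
        assert len(tr) == 15500 and len(te) == 1000

    def test_disjoint_and_complete(self):
        tr, te = split_dataset(100, seed=3)
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == 100

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_dataset(1)


class TestTraining:
    def _toy_data(self, n=12):
        rng = np.random.default_rng(5)
        levels = rng.uniform(0.2, 0.8, n)
        X = rng.normal(0, 1, (n, 2, 128, 128)).astype(np.float32) + levels[
            :, None, None, None
        ]
        Y = np.tile(levels[:, None, None], (1, 128, 128)).astype(np.float32)
        cond = np.array(["AC", "SoS"] * (n // 2))
        return X, cond, Y

    def test_identical_loss_curve_under_fixed_seed(self):
        X, cond, Y = self._toy_data()
        h = []
        for _ in range(2):
            net = ConditionalQUSNet(
                stage_channels=(2, 3, 4),
                branch_channels=(4, 3, 2, 2),
                input_channels=2,
                max_epochs=2,
                seed=17,
            )
            net.fit(X, Y, cond=cond)
            h.append(net.history_["train_loss"])
        np.testing.assert_array_equal(h[0], h[1])

    def test_empty_dataset_raises(self):
        net = ConditionalQUSNet()
        with pytest.raises(ValueError):
            net.fit(np.zeros((0, 2, 128, 128)), np.zeros((0, 128, 128)))

    def test_predict_before_fit_raises(self):
        net = ConditionalQUSNet()
        with pytest.raises(RuntimeError, match="not trained"):
            net.predict(np.zeros((1, 5, 128, 128)), cond=["AC"])

    def test_gradients_match_finite_differences(self):
        net = ConditionalQUSNet(
            stage_channels=(2, 3, 4),
            branch_channels=(4, 3, 2, 2),
            input_channels=2,
            seed=3,
            dropout_retention=1.0,
        )
        net._build()
        # float64 everywhere: float32 cancellation noise swamps the
        # finite differences at this loss magnitude
        for mod in net._modules().values():
            for pname, arr in mod.params().items():
                setattr(mod, pname if hasattr(mod, pname) else pname, arr)
            for pname in list(mod.grads):
                mod.grads[pname] = mod.grads[pname].astype(np.float64)
            if hasattr(mod, "w"):
                mod.w = mod.w.astype(np.float64)
                mod.b = mod.b.astype(np.float64)
            if hasattr(mod, "gamma"):
                mod.gamma = mod.gamma.astype(np.float64)
                mod.beta = mod.beta.astype(np.float64)
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (2, 2, 128, 128))
        y = rng.uniform(0, 1, (2, 128, 128))
        cond = np.array([0, 2])
        params, grads = net._param_dict()

        def loss_now():
            f, aux = net._forward(X, cond)
            aux_t = {r: nn.avg_pool(y[:, None], 128 // r)[:, 0] for r in net.RESOLUTIONS}
            return loss_qi(f, aux, y, aux_t, 0.0, [])[0], f, aux, aux_t

        net._zero_grads()
        _, f, aux, aux_t = loss_now()
        net._backward(
            2 * (f - y) / 2, {r: 2 * (aux[r] - aux_t[r]) / 2 for r in net.RESOLUTIONS}
        )
        check = np.random.default_rng(1)
        for key in ("enc0_conv.w", "enc1_norm.gamma", "br64_head.b", "out.w"):
            flat = params[key].ravel()
            i = check.integers(flat.size)
            eps, old = 1e-5, flat[i]
            flat[i] = old + eps
            up, *_ = loss_now()
            flat[i] = old - eps
            dn, *_ = loss_now()
            flat[i] = old
            numeric = (up - dn) / (2 * eps)
            analytic = grads[key].ravel()[i]
            assert numeric == pytest.approx(analytic, rel=5e-2, abs=1e-4)
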