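"""Unfolded-model wiring: stage algebra, shape/finite contracts,
determinism, checkpointing and the ablation variant."""

import dataclasses

import numpy as np
import pytest

import eegunfold as eu
from eegunfold.nn.autodiff import Tensor, mean_square, sub
from eegunfold.unfolding import NetD, NetN, NetR, UNet1d, PlainCNN


def zero_all(model):
    for p in model.parameters():
        p.data[...] = 0.0
    return model


class TestNetD:
    def test_zero_weights_give_residual_identity(self, rng):
        netd = NetD(UNet1d(eu.NetDConfig(depth=3, channels=(4, 8, 16)), rng))
        zero_all(netd)
        R = Tensor(rng.standard_normal((2, 1, 64)))
        N = Tensor(rng.standard_normal((2, 1, 64)))
        out = netd(R, N)
        assert np.array_equal(out.data, R.data - N.data)

    def test_shape_contract_512(self, rng):
        netd = NetD(UNet1d(eu.NetDConfig(), rng))
        out = netd(Tensor(rng.standard_normal((1, 1, 512))), Tensor(np.zeros((1, 1, 512))))
        assert out.data.shape == (1, 1, 512)

    def test_skip_ablation_changes_output(self, rng):
        x = rng.standard_normal((1, 1, 64))
        with_skips = UNet1d(eu.NetDConfig(depth=3, channels=(4, 8, 16), use_skips=True),
                            np.random.default_rng(3))
        without = UNet1d(eu.NetDConfig(depth=3, channels=(4, 8, 16), use_skips=False),
                         np.random.default_rng(3))
        a = with_skips(Tensor(x)).data
        b = without(Tensor(x)).data
        assert a.shape == b.shape
        assert np.linalg.norm(a - b) > 0


class TestNetN:
    def test_zero_g_with_zero_noise_and_perfect_d(self, rng):
        netn = NetN(eu.NetNConfig(n_layers=2, channels=4), rho_init=0.3, rng=rng)
        zero_all(netn.grad_net)
        R = Tensor(rng.standard_normal((1, 1, 32)))
        N = Tensor(np.zeros((1, 1, 32)))
        out = netn(R, N, R, delta=0.5, strict_surrogate=False)
        assert np.allclose(out.data, 0.0, atol=1e-14)

    def test_literal_update_algebra(self, rng):
        netn = NetN(eu.NetNConfig(n_layers=2, channels=4), rho_init=1.7, rng=rng)
        zero_all(netn.grad_net)
        netn.rho.data[...] = 1.7
        R = Tensor(rng.standard_normal((1, 1, 32)))
        N = Tensor(rng.standard_normal((1, 1, 32)))
        D = Tensor(rng.standard_normal((1, 1, 32)))
        out = netn(R, N, D, delta=0.5, strict_surrogate=False)
        assert np.allclose(out.data, 2 * (R.data - D.data) + N.data, atol=1e-14)

    def test_strict_surrogate_restores_half_weighting(self, rng):
        netn = NetN(eu.NetNConfig(n_layers=2, channels=4), rho_init=0.0, rng=rng)
        zero_all(netn.grad_net)
        R = Tensor(rng.standard_normal((1, 1, 32)))
        N = Tensor(rng.standard_normal((1, 1, 32)))
        D = Tensor(rng.standard_normal((1, 1, 32)))
        out = netn(R, N, D, delta=0.5, strict_surrogate=True)
        assert np.allclose(out.data, 0.5 * N.data + 0.5 * (R.data - D.data), atol=1e-14)

    def test_rho_scales_gradient_term_exactly(self, rng):
        netn = NetN(eu.NetNConfig(n_layers=2, channels=4), rho_init=0.0, rng=rng)
        R = Tensor(rng.standard_normal((1, 1, 32)))
        N = Tensor(rng.standard_normal((1, 1, 32)))
        D = Tensor(rng.standard_normal((1, 1, 32)))
        netn.rho.data[...] = 0.0
        out0 = netn(R, N, D, 0.5, False).data
        netn.rho.data[...] = 1.0
        out1 = netn(R, N, D, 0.5, False).data
        g = netn.grad_net(N).data
        assert np.allclose(out0 - out1, g, atol=1e-12)


class TestNetR:
    def test_near_identity_at_init(self, rng):
        netr = NetR(eu.NetRConfig(), rng)
        D = Tensor(rng.standard_normal((2, 1, 64)))
        N = Tensor(rng.standard_normal((2, 1, 64)))
        out = netr(D, N)
        assert np.allclose(out.data, D.data + N.data, atol=1e-6)

    def test_zero_input_zero_bias_gives_zero(self, rng):
        netr = NetR(eu.NetRConfig(), rng)
        for _, p in netr.named_parameters():
            if p.data.ndim == 1:  # biases
                p.data[...] = 0.0
        out = netr(Tensor(np.zeros((1, 1, 32))), Tensor(np.zeros((1, 1, 32))))
        assert np.allclose(out.data, 0.0, atol=1e-14)


class TestForward:
    def test_zero_network_is_identity_k1(self, rng):
        model = zero_all(eu.build_model(eu.UnfoldConfig(K=1), seed=0))
        y = rng.standard_normal((2, 512))
        out, traj = model.forward(y)
        assert np.array_equal(out.data[:, 0, :], y)
        assert np.array_equal(traj[0].D[:, 0, :], y)
        assert np.all(traj[0].N == 0.0)

    @pytest.mark.parametrize("K", [1, 3, 7])
    def test_trajectory_length(self, K, small_unfold_config, rng):
        cfg = dataclasses.replace(small_unfold_config, K=K)
        model = eu.build_model(cfg, seed=0)
        _, traj = model.forward(rng.standard_normal((1, 64)))
        assert len(traj) == K

    def test_all_stages_finite(self, small_unfold_config, rng):
        model = eu.build_model(small_unfold_config, seed=0)
        _, traj = model.forward(10 * rng.standard_normal((4, 128)))
        for st in traj:
            assert np.all(np.isfinite(st.R))
            assert np.all(np.isfinite(st.N))
            assert np.all(np.isfinite(st.D))

    def test_deterministic_init_and_forward(self, small_unfold_config, rng):
        y = rng.standard_normal((2, 128))
        a = eu.build_model(small_unfold_config, seed=42).forward(y)[0].data
        b = eu.build_model(small_unfold_config, seed=42).forward(y)[0].data
        assert np.array_equal(a, b)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            eu.UnfoldConfig(K=0)

    def test_incompatible_length_rejected(self, small_unfold_config):
        model = eu.build_model(small_unfold_config, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 130)))  # not divisible by 4

    def test_delta_fixed_rho_learnable(self, small_unfold_config, rng):
        model = eu.build_model(small_unfold_config, seed=0)
        names = [n for n, _ in model.named_parameters()]
        rhos = [n for n in names if n.endswith("rho")]
        assert len(rhos) == small_unfold_config.K - 1  # final half-stage has no noise update
        assert not any("delta" in n for n in names)

    def test_gradient_reaches_every_parameter(self, small_unfold_config, rng):
        model = eu.build_model(small_unfold_config, seed=1)
        y = rng.standard_normal((4, 128))
        x = rng.standard_normal((4, 128))
        out, _ = model.forward(y)
        loss = mean_square(sub(out, x[:, None, :]))
        model.zero_grad()
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0.0), name

    def test_output_modes_differ(self, small_unfold_config, rng):
        y = rng.standard_normal((1, 128))
        d_model = eu.build_model(small_unfold_config, seed=0)
        r_model = eu.build_model(
            dataclasses.replace(small_unfold_config, output_mode="R_last"), seed=0
        )
        assert not np.allclose(d_model.forward(y)[0].data, r_model.forward(y)[0].data)


class TestVariantAndCheckpoint:
    def test_cnn_variant_parameter_count_comparable(self, small_unfold_config):
        unet = eu.build_model(small_unfold_config, seed=0)
        cnn = eu.build_lrrnet_variant(small_unfold_config, seed=0)
        a = unet.stages[0].netd.num_parameters()
        b = cnn.stages[0].netd.num_parameters()
        assert 0.5 * a <= b <= 2.0 * a

    def test_variant_outputs_differ(self, small_unfold_config, rng):
        y = rng.standard_normal((1, 128))
        a = eu.build_model(small_unfold_config, seed=0).forward(y)[0].data
        b = eu.build_lrrnet_variant(small_unfold_config, seed=0).forward(y)[0].data
        assert b.shape == a.shape
        assert np.linalg.norm(a - b) > 0

    def test_checkpoint_roundtrip(self, small_unfold_config, rng, tmp_path):
        model = eu.build_model(small_unfold_config, seed=3)
        y = rng.standard_normal((2, 128))
        before = model.denoise(y)
        path = tmp_path / "model.npz"
        eu.save_checkpoint(model, path)
        restored = eu.load_checkpoint(path)
        assert restored.config == model.config
        assert np.array_equal(restored.denoise(y), before)

    def test_shared_weights_reduce_parameter_count(self, small_unfold_config):
        cfg = dataclasses.replace(small_unfold_config, K=4, output_mode="R_last")
        full = eu.build_model(cfg, seed=0).num_parameters()
        shared = eu.build_model(
            dataclasses.replace(cfg, share_weights_across_stages=True), seed=0
        ).num_parameters()
        assert shared < full
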