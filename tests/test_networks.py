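import numpy as np
import pytest

from dixonrecon.kspace import SamplingMask, fft3c, ifft3c
from dixonrecon.networks import (
    HalfUNet3D,
    NetworkConfig,
    UNet3D,
    UnrolledNetwork,
    crop_from_pool_grid,
    denormalize_two_channel,
    normalize_two_channel,
    pad_to_pool_grid,
    varnet_apply,
)
from dixonrecon.networks import autograd as ag
from dixonrecon.training import image_domain_mse_loss

from conftest import random_complex


# ---------------------------------------------------------------------------
# closed-form layer-arithmetic oracle, written independently of the package
# ---------------------------------------------------------------------------


def conv_p(cin, cout, k=3):
    return k**3 * cin * cout + cout


def unet_params_oracle(in_ch, stages, ch, interconnect=False):
    p = 0
    cin = in_ch
    for i in range(stages):
        cout = ch * 2**i
        p += conv_p(cin, cout) + conv_p(cout, cout)
        cin = cout
    for i in range(stages - 1, 0, -1):
        c_hi, c_lo = ch * 2**i, ch * 2 ** (i - 1)
        p += 8 * c_hi * c_lo + c_lo  # 2x2x2 transpose conv
        p += conv_p((3 if interconnect else 2) * c_lo, c_lo) + conv_p(c_lo, c_lo)
    return p + conv_p(ch, 2, k=1)


def half_params_oracle(in_ch, stages, ch, interconnect=False, upsampling="trilinear"):
    p = conv_p(in_ch, ch) + conv_p(ch, ch)
    p += (stages - 1) * 2 * conv_p(ch, ch)
    if upsampling == "transpose_conv":
        for i in range(1, stages):
            p += (2**i) ** 3 * ch * ch + ch
    p += conv_p((2 if interconnect else 1) * ch, ch) + conv_p(ch, ch)
    return p + conv_p(ch, 2, k=1)


def model_params_oracle(cfg: NetworkConfig):
    total = cfg.cascades  # mu scalars
    for it in range(cfg.cascades):
        in_ch = 2 * (it + 1) if cfg.is_dense else 2
        inter = cfg.is_dense and it > 0
        if cfg.is_half:
            total += half_params_oracle(
                in_ch, cfg.stages, cfg.base_channels, inter, cfg.upsampling
            )
        else:
            total += unet_params_oracle(in_ch, cfg.stages, cfg.base_channels, inter)
    return total


# ---------------------------------------------------------------------------


class TestPadToPoolGrid:
    def test_acquisition_matrix_shape(self):
        x = np.zeros((2, 128, 128, 36))
        padded, pads = pad_to_pool_grid(x, stages=5)
        assert padded.shape == (2, 128, 128, 48)

    def test_already_multiple_identity(self):
        x = np.arange(2 * 16 * 16 * 16, dtype=float).reshape(2, 16, 16, 16)
        padded, pads = pad_to_pool_grid(x, stages=5)
        assert padded.shape == x.shape
        assert np.array_equal(padded, x)

    @pytest.mark.parametrize("shape", [(2, 5, 9, 3), (2, 17, 30, 7), (1, 8, 8, 8)])
    def test_round_trip(self, rng, shape):
        x = rng.normal(size=shape)
        padded, pads = pad_to_pool_grid(x, stages=4)
        assert all(n % 8 == 0 for n in padded.shape[1:])
        assert np.array_equal(crop_from_pool_grid(padded, pads), x)


class TestNormalizeTwoChannel:
    def test_zero_mean_unit_sd(self, rng):
        x = rng.normal(size=(2, 8, 8, 4)) * 5 + 2
        y, m, s = normalize_two_channel(x)
        assert y.mean() == pytest.approx(0, abs=1e-12)
        assert y.std() == pytest.approx(1, abs=1e-12)

    def test_constant_sentinel(self):
        x = np.full((2, 4, 4, 4), 2.5)
        y, m, s = normalize_two_channel(x)
        assert np.abs(y).max() == 0
        assert s == 1.0
        assert np.allclose(denormalize_two_channel(y, m, s), x)

    def test_round_trip(self, rng):
        x = rng.normal(size=(2, 8, 8, 4))
        y, m, s = normalize_two_channel(x)
        assert np.abs(denormalize_two_channel(y, m, s) - x).max() < 1e-6


class TestUNet3D:
    def test_reference_parameter_count(self):
        net = UNet3D(2, 5, 32, 0.25, np.random.default_rng(0))
        assert net.n_parameters() == 22_576_226
        assert net.n_parameters() == unet_params_oracle(2, 5, 32)

    def test_zero_weights_zero_output(self, rng):
        net = UNet3D(2, 3, 4, 0.0, np.random.default_rng(0))
        for p in net.parameters():
            p.data[...] = 0
        out, _ = net(ag.Tensor(rng.normal(size=(2, 8, 8, 4)).astype(np.float32)))
        assert np.abs(out.data).max() == 0

    def test_shape_preserved(self, rng):
        net = UNet3D(2, 4, 4, 0.0, np.random.default_rng(0))
        out, cache = net(ag.Tensor(rng.normal(size=(2, 32, 32, 16)).astype(np.float32)))
        assert out.shape == (2, 32, 32, 16)
        assert len(cache) == 3  # one feature per decoder stage

    def test_unpadded_input_rejected(self, rng):
        net = UNet3D(2, 4, 4, 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            net(ag.Tensor(np.zeros((2, 10, 8, 8), dtype=np.float32)))


class TestHalfUNet3D:
    def test_reference_parameter_count(self):
        net = HalfUNet3D(2, 5, 32, 0.25, np.random.default_rng(0))
        assert net.n_parameters() == 306_306
        # explicit arithmetic: first conv + nine ch->ch convs + final block + 1x1x1
        assert net.n_parameters() == 1_760 + 9 * 27_680 + 55_360 + 66

    def test_zero_weights_zero_output(self, rng):
        net = HalfUNet3D(2, 3, 4, 0.0, np.random.default_rng(0))
        for p in net.parameters():
            p.data[...] = 0
        out, _ = net(ag.Tensor(rng.normal(size=(2, 8, 8, 4)).astype(np.float32)))
        assert np.abs(out.data).max() == 0

    def test_trilinear_adds_no_parameters(self):
        tri = HalfUNet3D(2, 4, 8, 0.0, np.random.default_rng(0), upsampling="trilinear")
        base = half_params_oracle(2, 4, 8)
        assert tri.n_parameters() == base

    def test_transpose_conv_param_blowup_in_cascaded_model(self):
        n_tri = UnrolledNetwork(NetworkConfig("halfvarnet", 8)).n_parameters()
        n_tc = model_params_oracle(NetworkConfig("halfvarnet", 8, upsampling="transpose_conv"))
        assert 15 <= n_tc / n_tri <= 25  # "a factor of 20" ablation


class TestUnrolledNetwork:
    @pytest.mark.parametrize("variant", ["varnet", "halfvarnet", "dircn", "halfdircn"])
    def test_shape_preservation(self, rng, variant):
        cfg = NetworkConfig(variant, cascades=2, base_channels=2, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0).eval()
        k = random_complex(rng, (8, 8, 4))
        mask = SamplingMask(np.ones((8, 4), dtype=np.uint8), 1.0, 1.0)
        out = net.forward(k, mask)
        assert out.shape == (2, 8, 8, 4)

    def test_parameter_additivity(self):
        cfg = NetworkConfig("dircn", cascades=3, base_channels=2, stages=3, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0)
        per_cascade = [r.n_parameters() for r in net.regularizers]
        assert net.n_parameters() == sum(per_cascade) + cfg.cascades

    def test_parameter_count_oracle_random_configs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            cfg = NetworkConfig(
                variant=rng.choice(["varnet", "halfvarnet", "dircn", "halfdircn"]),
                cascades=int(rng.integers(1, 4)),
                base_channels=int(rng.integers(1, 7)),
                stages=int(rng.integers(2, 5)),
                dropout=0.0,
                upsampling=rng.choice(["trilinear", "transpose_conv"]),
            )
            net = UnrolledNetwork(cfg, seed=0)
            assert net.n_parameters() == model_params_oracle(cfg), cfg

    def test_zero_weight_dc_fidelity(self, rng, small_mask):
        cfg = NetworkConfig("halfvarnet", cascades=3, base_channels=4, stages=3, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0).eval()
        for reg in net.regularizers:
            for p in reg.parameters():
                p.data[...] = 0
        for p in net.mus:
            p.data[...] = 0.37
        k = random_complex(rng, (32, 32, 8))
        k_us = (k * small_mask.broadcast(32)).astype(np.complex64)  # working precision
        _, kf = net.forward(k_us, small_mask, return_kspace=True)
        kfc = kf.data[0] + 1j * kf.data[1]
        assert np.abs((kfc - k_us) * small_mask.broadcast(32)).max() == 0

    def test_one_cascade_zero_weights_full_mask_identity(self, rng):
        cfg = NetworkConfig("varnet", cascades=1, base_channels=2, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0).eval()
        for reg in net.regularizers:
            for p in reg.parameters():
                p.data[...] = 0
        k = random_complex(rng, (8, 8, 4)).astype(np.complex64)
        mask = SamplingMask(np.ones((8, 4), dtype=np.uint8), 1.0, 1.0)
        out = net.reconstruct(k, mask)
        assert np.abs(out - ifft3c(k)).max() < 1e-6

    def test_single_cascade_matches_hand_unrolled_equation(self, rng):
        """One cascade with a stub regularizer equals the hand-stepped update."""
        cfg = NetworkConfig("varnet", cascades=1, base_channels=2, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0).eval()
        net.mus[0].data[...] = 0.7

        class Stub:
            def __call__(self, x, prev_cache=None):
                return ag.mul_const(x, 0.5), None

            def parameters(self):
                return []

        net.regularizers[0] = Stub()
        plane = (np.random.default_rng(3).random((8, 4)) < 0.6).astype(np.uint8)
        mask = SamplingMask(plane, 1.7, 0.1)
        k = random_complex(rng, (8, 8, 4))
        k_us = (k * mask.broadcast(8)).astype(np.complex64)
        got = net.reconstruct(k_us, mask)

        # hand-unrolled: k2 = k1 - mu*D(k1 - kus) + F(denorm(0.5*norm(F^H k1)))
        img = ifft3c(k_us)
        two = np.stack([img.real, img.imag]).astype(np.float32)
        m, s = two.mean(), two.std()
        reg_out = (0.5 * (two - m) / s) * s  # stub then scale-only denorm
        model_k = fft3c(reg_out[0] + 1j * reg_out[1])
        k2 = k_us - 0.7 * mask.broadcast(8) * (k_us - k_us) + model_k
        expect = ifft3c(k2)
        assert np.abs(got - expect).max() < 1e-5

    def test_dense_input_channel_arithmetic(self):
        cfg = NetworkConfig("halfdircn", cascades=5, base_channels=2, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0)
        first_convs = [reg.enc_blocks[0].block.mods[0] for reg in net.regularizers]
        assert [c.in_channels for c in first_convs] == [2, 4, 6, 8, 10]

    def test_interconnect_final_block_widened(self):
        cfg = NetworkConfig("halfdircn", cascades=3, base_channels=4, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0)
        widths = [reg.final_block.block.mods[0].in_channels for reg in net.regularizers]
        assert widths == [4, 8, 8]

    def test_gradient_liveness(self, rng):
        cfg = NetworkConfig("halfvarnet", cascades=2, base_channels=2, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0)
        k = random_complex(rng, (8, 8, 4))
        plane = (np.random.default_rng(1).random((8, 4)) < 0.5).astype(np.uint8)
        mask = SamplingMask(plane, 2.0, 0.1)
        k_us = k * mask.broadcast(8)
        _, pred_k = net.forward(k_us, mask, return_kspace=True)
        loss = image_domain_mse_loss(pred_k, ifft3c(k))
        loss.backward()
        dead_ok = {"mus.0"}  # mu_1 multiplies D(k_1 - k_us) == 0: structurally dead
        for name, p in net.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            if name in dead_ok:
                continue
            if name.endswith("bias") and ".block.mods.0." in name or ".block.mods.4." in name:
                # conv bias directly followed by instance norm: provably zero
                continue
            assert np.abs(p.grad).max() > 0, name

    def test_invalid_variant_for_apply(self, rng, small_mask):
        cfg = NetworkConfig("dircn", cascades=1, base_channels=2, stages=2, dropout=0.0)
        k = random_complex(rng, (32, 32, 8)) * small_mask.broadcast(32)
        with pytest.raises(ValueError):
            varnet_apply(k, small_mask, cfg)

    def test_mask_shape_mismatch(self, rng, small_mask):
        cfg = NetworkConfig("varnet", cascades=1, base_channels=2, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0)
        with pytest.raises(ValueError):
            net.forward(random_complex(rng, (8, 8, 4)), small_mask)

    def test_cascades_below_one_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig("varnet", cascades=0)

    def test_cascade_trace(self, rng, small_mask):
        from dixonrecon.networks import CascadeTrace

        k = random_complex(rng, (32, 32, 8)) * small_mask.broadcast(32)
        cfg = NetworkConfig("halfdircn", cascades=3, base_channels=2, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0).eval()
        _, trace = net.forward(k, small_mask, return_trace=True)
        assert isinstance(trace, CascadeTrace)
        assert len(trace.image_history) == 3  # one iterate per cascade
        assert trace.decoder_cache is not None
        assert len(trace.mu_list) == 3

        cfg = NetworkConfig("halfvarnet", cascades=2, base_channels=2, stages=2, dropout=0.0)
        net = UnrolledNetwork(cfg, seed=0).eval()
        _, trace = net.forward(k, small_mask, return_trace=True)
        assert trace.decoder_cache is None  # non-dense variants keep no cache

    def test_state_dict_round_trip(self, rng, small_mask):
        cfg = NetworkConfig("halfvarnet", cascades=2, base_channels=2, stages=2, dropout=0.0)
        a = UnrolledNetwork(cfg, seed=0)
        b = UnrolledNetwork(cfg, seed=99)
        b.load_state_dict(a.state_dict())
        k = random_complex(rng, (32, 32, 8)) * small_mask.broadcast(32)
        ra = a.reconstruct(k, small_mask)
        rb = b.reconstruct(k, small_mask)
        assert np.array_equal(ra, rb)
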