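"""Network construction, parameter accounting, init, normalization."""

import numpy as np
import pytest

from munet import nets
from munet._conv import conv3d, upsample2_linear, upsample2_linear_adjoint


class TestLayerApply:
    def test_zero_weights_sigmoid_gives_half(self):
        x = np.random.default_rng(0).random((3, 6, 6, 6)).astype(np.float32)
        W = np.zeros((2, 3, 3, 3, 3), np.float32)
        out = nets.layer_apply(x, W, np.zeros(2, np.float32), "sigmoid")
        assert np.allclose(out, 0.5)

    def test_zero_weights_elu_gives_zero(self):
        x = np.random.default_rng(0).random((3, 6, 6, 6)).astype(np.float32)
        W = np.zeros((1, 3, 1, 1, 1), np.float32)
        out = nets.layer_apply(x, W, np.zeros(1, np.float32), "elu")
        assert np.allclose(out, 0.0)

    def test_identity_convolution(self):
        x = np.random.default_rng(0).random((1, 6, 6, 6)).astype(np.float32)
        W = np.ones((1, 1, 1, 1, 1), np.float32)
        out = nets.layer_apply(x, W, np.zeros(1, np.float32), "linear")
        assert np.allclose(out, x, atol=1e-7)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            nets.layer_apply(np.zeros((2, 4, 4, 4), np.float32),
                             np.zeros((1, 3, 1, 1, 1), np.float32),
                             np.zeros(1, np.float32), "linear")


def _enumerate_parameters(spec: nets.MuNetSpec) -> int:
    """Independent oracle: count weight-tensor entries one by one."""
    ws = nets.he_init(spec, seed=0)
    return sum(int(np.prod(k.shape)) + int(np.prod(b.shape))
               for k, b in zip(ws.kernels, ws.biases))


class TestAccounting:
    def test_default_parameter_count(self):
        assert nets.count_parameters(nets.MuNetSpec()) == 43_745

    def test_minimal_spec(self):
        spec = nets.MuNetSpec(in_channels=1, layers=[nets.LayerSpec(1, 1, "elu")])
        assert nets.count_parameters(spec) == 2

    def test_two_layer_hand_count(self):
        spec = nets.MuNetSpec(in_channels=1, layers=[
            nets.LayerSpec(2, 3, "sigmoid"), nets.LayerSpec(1, 1, "elu")])
        assert nets.count_parameters(spec) == (27 + 1) * 2 + (2 + 1) * 1 == 59

    @pytest.mark.parametrize("seed", range(5))
    def test_formula_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_layers = int(rng.integers(1, 4))
        layers = [nets.LayerSpec(int(rng.integers(1, 9)),
                                 int(rng.choice([1, 3, 5])), "sigmoid")
                  for _ in range(n_layers - 1)]
        layers.append(nets.LayerSpec(1, int(rng.choice([1, 3])), "elu"))
        spec = nets.MuNetSpec(in_channels=int(rng.integers(1, 5)), layers=layers)
        assert nets.count_parameters(spec) == _enumerate_parameters(spec)

    def test_default_receptive_field(self):
        assert nets.receptive_field(nets.MuNetSpec()) == 7

    def test_receptive_field_trivial(self):
        spec = nets.MuNetSpec(in_channels=1, layers=[nets.LayerSpec(1, 1, "elu")])
        assert nets.receptive_field(spec) == 1

    @pytest.mark.parametrize("widths,expected", [((3, 3), 5), ((5, 3, 1), 7),
                                                 ((3, 1), 3)])
    def test_receptive_field_perturbation_oracle(self, widths, expected):
        """Perturb one input voxel; measure the output support width."""
        layers = [nets.LayerSpec(2, w, "linear") for w in widths[:-1]]
        layers.append(nets.LayerSpec(1, widths[-1], "linear"))
        spec = nets.MuNetSpec(in_channels=1, layers=layers)
        assert nets.receptive_field(spec) == expected
        net = nets.MuNet(spec, seed=3)
        n = expected + 6
        base = np.zeros((1, 1, n, n, n), np.float32)
        x = base.copy()
        x[0, 0, n // 2, n // 2, n // 2] = 1.0
        diff = np.abs(net.forward(x) - net.forward(base))[0, 0]
        support = np.where(diff.sum(axis=(1, 2)) > 1e-7)[0]
        assert support[-1] - support[0] + 1 == expected


class TestHeInit:
    def test_biases_zero_and_deterministic(self):
        ws1 = nets.he_init(nets.MuNetSpec(), seed=5)
        ws2 = nets.he_init(nets.MuNetSpec(), seed=5)
        for b in ws1.biases:
            assert np.all(b == 0)
        for a, b in zip(ws1.kernels, ws2.kernels):
            assert np.array_equal(a, b)

    def test_layer2_std(self):
        """Printed convention: std sqrt(2/n_{j-1}) with no kernel volume."""
        ws = nets.he_init(nets.MuNetSpec(), seed=1)
        assert ws.kernels[1].std() == pytest.approx(np.sqrt(2 / 32), rel=0.05)

    def test_standard_fan_in_variant(self):
        ws = nets.he_init(nets.MuNetSpec(), seed=1, fan_in="standard")
        assert ws.kernels[1].std() == pytest.approx(np.sqrt(2 / (32 * 27)), rel=0.05)

    def test_seed_sensitivity(self):
        a = nets.he_init(nets.MuNetSpec(), seed=1)
        b = nets.he_init(nets.MuNetSpec(), seed=2)
        assert not np.array_equal(a.kernels[0], b.kernels[0])


class TestNormalization:
    def _channels(self, rng):
        shape = (12, 12, 12)
        mlem = rng.random(shape) * 3 + 1
        rm = rng.random(shape) * 2 + 0.5
        t1 = rng.random(shape) + 0.2
        return mlem, rm, t1

    def test_standardized_stats(self, rng):
        mlem, rm, t1 = self._channels(rng)
        x, norm = nets.normalize_inputs(mlem, rm, t1, nlm_omega=0.5)
        for i in range(3):
            assert abs(x[i].mean()) < 1e-6
            assert abs(x[i].astype(np.float64).var() - 1) < 1e-5

    def test_round_trip(self, rng):
        mlem, rm, t1 = self._channels(rng)
        x, norm = nets.normalize_inputs(mlem, rm, t1, nlm_omega=0.5)
        back = x[0].astype(np.float64) * norm.scales["mlem"] + norm.offsets["mlem"]
        assert np.allclose(back, mlem, atol=1e-6)

    def test_nlm_channel_not_restandardized(self, rng):
        """The NLM of the standardized RM channel keeps its own mean."""
        mlem, rm, t1 = self._channels(rng)
        t1 = t1 + 5.0 * (np.arange(12)[None, None, :] > 5)  # strong edge
        x, _ = nets.normalize_inputs(mlem, rm, t1, nlm_omega=0.1)
        assert abs(x[3].mean()) > 1e-4 or abs(x[3].astype(np.float64).var() - 1) > 1e-3

    def test_constant_channel_rejected(self, rng):
        mlem, rm, t1 = self._channels(rng)
        with pytest.raises(ValueError, match="constant"):
            nets.normalize_inputs(np.ones_like(mlem), rm, t1, nlm_omega=0.5)

    def test_rescale_output_contract(self, rng):
        mlem, rm, t1 = self._channels(rng)
        x, norm = nets.normalize_inputs(mlem, rm, t1, nlm_omega=0.5)
        pred = rng.random(mlem.shape) + 0.1
        out = nets.rescale_output(pred, norm)
        assert out.sum() == pytest.approx(mlem.sum(), rel=1e-10)
        out2 = nets.rescale_output(2 * pred, norm)
        assert np.allclose(out2, out, rtol=1e-10)

    def test_rescale_zero_sum_rejected(self, rng):
        mlem, rm, t1 = self._channels(rng)
        _, norm = nets.normalize_inputs(mlem, rm, t1, nlm_omega=0.5)
        with pytest.raises(ValueError, match="zero"):
            nets.rescale_output(np.zeros((4, 4, 4)), norm)


class TestMuNetForward:
    def test_translation_equivariance_interior(self):
        """Stride-1 zero-padded net: shifting the input shifts the output."""
        net = nets.build_munet(nets.MuNetSpec(
            in_channels=2, layers=[nets.LayerSpec(4, 3, "sigmoid"),
                                   nets.LayerSpec(1, 3, "elu")]), seed=2)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 2, 12, 12, 12)).astype(np.float32)
        xs = np.roll(x, 1, axis=2)
        y = net.forward(x)[0, 0]
        ys = net.forward(xs)[0, 0]
        c = slice(3, -3)
        assert np.allclose(np.roll(y, 1, axis=0)[c, c, c], ys[c, c, c], atol=1e-5)

    def test_weight_roundtrip(self):
        net = nets.build_munet(seed=4)
        ws = net.get_weights()
        net2 = nets.build_munet(seed=9)
        net2.set_weights(ws)
        x = np.random.default_rng(1).random((1, 4, 8, 8, 8)).astype(np.float32)
        assert np.allclose(net.forward(x), net2.forward(x))


class TestUNet:
    def test_zero_weights_residual_passthrough(self):
        un = nets.build_unet(seed=0)
        for l in un.layers:
            l.W[...] = 0
            l.b[...] = 0
        x = np.random.default_rng(0).normal(size=(1, 4, 16, 16, 16)) \
            .astype(np.float32)
        out = un.forward(x)
        assert np.allclose(out[0, 0], x[0, 3], atol=1e-7)

    def test_output_shape_and_param_count(self):
        un = nets.build_unet(seed=0)
        x = np.zeros((1, 4, 16, 16, 16), np.float32)
        assert un.forward(x).shape == (1, 1, 16, 16, 16)
        assert un.n_parameters() > nets.count_parameters(nets.MuNetSpec())

    def test_indivisible_shape_rejected(self):
        un = nets.build_unet(seed=0)
        with pytest.raises(ValueError, match="divisible"):
            un.forward(np.zeros((1, 4, 20, 20, 20), np.float32))

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        spec = nets.UNetSpec(encoder_kernels=(3, 4), decoder_kernels=(3, 1))
        un = nets.UNet(spec, seed=3, fan_in="standard")
        x = (rng.normal(size=(1, 4, 8, 8, 8)) * 0.5).astype(np.float32)
        dy = rng.normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        un.forward(x)
        un.backward(dy)
        dirs = [rng.normal(size=p.shape).astype(np.float32) for p in un.parameters()]
        analytic = sum((g * d).sum() for g, d in zip(un.gradients(), dirs))
        eps = 1e-3
        for p, d in zip(un.parameters(), dirs):
            p += eps * d
        fp = (un.forward(x) * dy).sum()
        for p, d in zip(un.parameters(), dirs):
            p -= 2 * eps * d
        fm = (un.forward(x) * dy).sum()
        numeric = (fp - fm) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=0.02)


class TestUpsampling:
    def test_doubles_shape_and_preserves_constants(self):
        x = np.ones((1, 2, 4, 5, 6), np.float32)
        y = upsample2_linear(x)
        assert y.shape == (1, 2, 8, 10, 12)
        assert np.allclose(y, 1.0)

    def test_adjointness(self, rng):
        x = rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float32)
        y = rng.normal(size=(1, 3, 8, 8, 8)).astype(np.float32)
        lhs = (upsample2_linear(x) * y).sum()
        rhs = (x * upsample2_linear_adjoint(y)).sum()
        assert lhs == pytest.approx(rhs, rel=1e-4)
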