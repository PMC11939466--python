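import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import signal

from oednet.network import (ArchitectureConfig, ConvBlockConfig, Dropout,
                            LABELS, PROPOSED, ablation_table,
                            atrous_convolve_reference, build_network,
                            count_parameters, global_pool, infer_shapes,
                            make_architecture)

finite_maps = arrays(
    np.float64,
    st.tuples(st.integers(1, 4), st.integers(1, 5), st.integers(1, 5)),
    elements=st.floats(-20, 20, allow_nan=False),
)


class TestAtrousReference:
    def test_dilation_two_receptive_field(self, rng):
        """A 3x3 kernel at dilation 2 sees a 5x5 field with only 9 weights:
        a 5x5 input yields a single output."""
        x = np.ones((5, 5))
        out = atrous_convolve_reference(x, np.ones((3, 3)), dilation=2)
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(9.0)

    def test_dilation_one_equals_standard_correlation(self, rng):
        x = rng.normal(size=(8, 9))
        k = rng.normal(size=(3, 3))
        ours = atrous_convolve_reference(x, k, dilation=1)
        scipy_out = signal.correlate2d(x, k, mode="valid")
        np.testing.assert_allclose(ours, scipy_out, atol=1e-12)

    def test_output_shrinks_by_dilated_span(self, rng):
        out = atrous_convolve_reference(rng.normal(size=(11, 13)),
                                        rng.normal(size=(3, 3)), dilation=3)
        assert out.shape == (11 - 6, 13 - 6)

    def test_too_small_input_errors_with_minimum(self):
        with pytest.raises(ValueError, match="5x5"):
            atrous_convolve_reference(np.ones((4, 4)), np.ones((3, 3)), 2)


class TestFrameworkConvMatchesOracle:
    @pytest.mark.parametrize("dilation", [1, 2, 3])
    @pytest.mark.parametrize("kernel_side", [1, 3])
    def test_layer_equals_reference(self, dilation, kernel_side, rng):
        """The im2col layer and the loop-based reference agree on random
        9x9 inputs."""
        from oednet.network import DilatedConv2d
        x = rng.normal(size=(9, 9)).astype(np.float32)
        k = rng.normal(size=(kernel_side, kernel_side)).astype(np.float32)
        layer = DilatedConv2d(1, 1, kernel_side, dilation,
                              np.random.default_rng(0))
        layer.weight.data[0, 0] = k
        layer.bias.data[:] = 0.0
        out = layer.forward(x[None, None], training=False)[0, 0]
        ref = atrous_convolve_reference(x, k, dilation)
        np.testing.assert_allclose(out, ref, atol=1e-5)


class TestGlobalPooling:
    def test_hand_computed_values(self):
        maps = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert global_pool(maps, "GAP")[0] == pytest.approx(2.5)
        assert global_pool(maps, "GMP")[0] == pytest.approx(4.0)
        assert global_pool(maps, "GLSEP")[0] == pytest.approx(
            np.log(np.exp(1) + np.exp(2) + np.exp(3) + np.exp(4)), abs=1e-9)
        assert global_pool(maps, "GLSEP")[0] == pytest.approx(4.4402,
                                                              abs=1e-4)

    def test_constant_map_collapses(self):
        maps = np.full((2, 3, 5), 1.7)
        np.testing.assert_allclose(global_pool(maps, "GAP"), 1.7)
        np.testing.assert_allclose(global_pool(maps, "GMP"), 1.7)

    @settings(max_examples=50, deadline=None)
    @given(finite_maps)
    def test_lse_bounds_and_brute_force(self, maps):
        """GMP <= GLSEP <= GMP + log(F1*F2), and each variant matches its
        one-line definition."""
        gap, gmp, glsep = (global_pool(maps, v)
                           for v in ("GAP", "GMP", "GLSEP"))
        f = maps.shape[1] * maps.shape[2]
        assert (gmp <= glsep + 1e-9).all()
        assert (glsep <= gmp + np.log(f) + 1e-9).all()
        np.testing.assert_allclose(gap, maps.mean(axis=(1, 2)), atol=1e-9)
        np.testing.assert_allclose(gmp, maps.max(axis=(1, 2)), atol=1e-9)
        np.testing.assert_allclose(
            glsep,
            np.log(np.exp(maps).sum(axis=(1, 2))), rtol=1e-9, atol=1e-9)

    def test_lse_shift_invariance(self, rng):
        maps = rng.normal(size=(3, 4, 4))
        shifted = global_pool(maps + 500.0, "GLSEP") - 500.0
        np.testing.assert_allclose(shifted, global_pool(maps, "GLSEP"),
                                   atol=1e-9)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            global_pool(np.zeros((1, 0, 3)), "GAP")


class TestParameterCounting:
    def test_proposed_network_total(self):
        """The five-block reference configuration has exactly 1,014,867
        trainable parameters, in closed form and in the built model."""
        assert count_parameters(PROPOSED) == 1_014_867
        assert build_network(PROPOSED, seed=0).num_parameters() == 1_014_867

    def test_first_block_parameters(self):
        one_block = ArchitectureConfig(blocks=(ConvBlockConfig(16),),
                                       hidden_width=1, input_side=8)
        head = 16 * 1 + 1 + 1 * 3 + 3
        assert count_parameters(one_block) - head == 784

    def test_classifier_only(self):
        cfg = ArchitectureConfig(blocks=(), hidden_width=4, input_side=2)
        assert count_parameters(cfg) == 31
        assert build_network(cfg).num_parameters() == 31

    def test_bn_toggle_removes_affine_terms(self):
        with_bn = make_architecture(channels=(8, 16), bn=True, h1=4,
                                    input_side=32)
        without = make_architecture(channels=(8, 16), bn=False, h1=4,
                                    input_side=32)
        assert (count_parameters(with_bn) - count_parameters(without)
                == 4 * (8 + 16))

    @pytest.mark.parametrize("arch_id,config", ablation_table())
    def test_closed_form_matches_built_model(self, arch_id, config):
        assert count_parameters(config) == \
            build_network(config, seed=0).num_parameters()


class TestShapeInference:
    def test_table_shapes(self):
        shapes = {s.stage: s for s in infer_shapes(PROPOSED)}
        assert (shapes["block1.conv1"].channels,
                shapes["block1.conv1"].height) == (16, 348)
        assert shapes["block1.pool"].height == 174
        assert (shapes["block5.pool"].channels,
                shapes["block5.pool"].height,
                shapes["block5.pool"].width) == (256, 9, 9)
        assert shapes["global_pool"].channels == 256

    def test_pointwise_conv_preserves_side(self):
        cfg = ArchitectureConfig(
            blocks=(ConvBlockConfig(4, w1=1, w2=1, l1=5, l2=7),),
            hidden_width=4, input_side=20)
        shapes = infer_shapes(cfg)
        assert shapes[0].height == 20
        assert shapes[1].height == 20

    def test_underflow_error_names_block(self):
        cfg = ArchitectureConfig(
            blocks=(ConvBlockConfig(4), ConvBlockConfig(8, l1=9)),
            hidden_width=4, input_side=16)
        with pytest.raises(ValueError, match="block 2"):
            infer_shapes(cfg)


class TestForward:
    def test_output_is_probability_vector(self, rng):
        cfg = make_architecture(channels=(4, 8), h1=8, input_side=20)
        net = build_network(cfg, seed=1)
        x = rng.normal(size=(5, 3, 20, 20)).astype(np.float32)
        probs = net.predict_proba(x)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (5, len(LABELS))

    def test_dropout_identity_at_evaluation(self, rng):
        layer = Dropout(0.5, np.random.default_rng(0))
        x = rng.normal(size=(4, 10)).astype(np.float32)
        np.testing.assert_array_equal(layer.forward(x, training=False), x)
        # and training mode scales survivors by 1/(1-p)
        out = layer.forward(x, training=True)
        nz = out != 0
        np.testing.assert_allclose(out[nz], x[nz] * 2.0, rtol=1e-6)

    def test_inference_is_deterministic_with_dropout_configured(self, rng):
        cfg = make_architecture(channels=(4,), h1=8, p=0.5, input_side=12)
        net = build_network(cfg, seed=2)
        x = rng.normal(size=(3, 3, 12, 12)).astype(np.float32)
        np.testing.assert_array_equal(net.predict_proba(x),
                                      net.predict_proba(x))

    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = make_architecture(channels=(4,), h1=8, input_side=12)
        net = build_network(cfg, seed=3)
        x = rng.normal(size=(2, 3, 12, 12)).astype(np.float32)
        before = net.predict_proba(x)
        net.save(tmp_path / "m.npz")
        from oednet.network import Network
        loaded = Network.load(tmp_path / "m.npz")
        np.testing.assert_allclose(loaded.predict_proba(x), before,
                                   atol=1e-7)


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of the weighted cross-entropy loss agree with
        central differences in float64 (biases randomized away from the
        ReLU kinks that zero initialization would otherwise sit on)."""
        cfg = ArchitectureConfig(
            blocks=(ConvBlockConfig(4, l1=2), ConvBlockConfig(6)),
            global_pool="GLSEP", hidden_width=8, input_side=20)
        net = build_network(cfg, seed=3)
        net.set_compute_dtype(np.float64)
        r0 = np.random.default_rng(11)
        for p in net.params():
            p.data = p.data.astype(np.float64)
            if p.data.ndim == 1:
                p.data[...] = r0.normal(0, 0.1, size=p.data.shape)
        rng = np.random.default_rng(0)
        n = 4
        x = rng.normal(size=(n, 3, 20, 20))
        y = rng.integers(0, 3, size=n)
        w = np.array([1.0, 0.7, 1.3])

        def loss_and_grad():
            logits = np.asarray(net.forward(x, training=True),
                                dtype=np.float64)
            m = logits.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
            loss = (-w[y] * (logits[np.arange(n), y] - lse)).mean()
            p = np.exp(logits - lse[:, None])
            return loss, (w[y][:, None] * (p - np.eye(3)[y])) / n

        net.zero_grad()
        _, g = loss_and_grad()
        net.backward(g)
        check_rng = np.random.default_rng(5)
        for p in net.params():
            for _ in range(3):
                idx = tuple(check_rng.integers(0, s) for s in p.data.shape)
                eps = 1e-6
                old = float(p.data[idx])
                p.data[idx] = old + eps
                up, _ = loss_and_grad()
                p.data[idx] = old - eps
                down, _ = loss_and_grad()
                p.data[idx] = old
                numeric = (up - down) / (2 * eps)
                assert p.grad[idx] == pytest.approx(numeric, rel=1e-3,
                                                    abs=1e-7)
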