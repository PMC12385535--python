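"""Architecture-level contracts: conv geometry, token layout, end-to-end
forward behavior, and the parameter census."""

import numpy as np
import pytest

from skinformer.model import (
    HybridSkinFormer,
    ModelConfig,
    conv_output_dims,
    count_parameters,
    format_parameter_report,
    test_scale_config as scale_config,
)
from skinformer.nn import Linear

PAPER_SCHEDULE = ModelConfig().conv_schedule()


def brute_force_dims(schedule, h, w):
    """Count the valid sliding-window placements layer by layer."""
    for k, s, _ in schedule:
        if h < k or w < k:
            return None
        h = len(range(0, h - k + 1, s))
        w = len(range(0, w - k + 1, s))
    return h, w


class TestConvGeometry:
    def test_reference_input_gives_21x33(self):
        assert conv_output_dims(PAPER_SCHEDULE, 784, 1216) == (21, 33)

    def test_64x64_collapses_to_single_position(self):
        assert conv_output_dims(PAPER_SCHEDULE, 64, 64) == (1, 1)

    def test_63x63_fails_at_layer_3(self):
        with pytest.raises(ValueError, match="layer 3"):
            conv_output_dims(PAPER_SCHEDULE, 63, 63)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            conv_output_dims(PAPER_SCHEDULE, 0, 100)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            schedule = [
                (int(rng.integers(1, 8)), int(rng.integers(1, 5)), 1)
                for _ in range(int(rng.integers(1, 4)))
            ]
            h, w = int(rng.integers(1, 120)), int(rng.integers(1, 120))
            expected = brute_force_dims(schedule, h, w)
            if expected is None:
                with pytest.raises(ValueError):
                    conv_output_dims(schedule, h, w)
            else:
                assert conv_output_dims(schedule, h, w) == expected


class TestConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=10, head_num=3)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_height=20, input_width=20)

    def test_round_trip(self):
        cfg = scale_config()
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


@pytest.fixture(scope="module")
def token_model():
    """Config whose feature map is 2x3 so the attention stack sees 6 tokens."""
    cfg = ModelConfig(hidden_dim=2, embed_dim=6, head_num=2, atten_layer_num=2,
                      classes_num=4, input_height=112, input_width=160)
    return HybridSkinFormer(cfg, seed=5)


class TestForward:
    def test_conv_stem_output_shape(self, token_model, rng):
        x = rng.random((2, 5, 112, 160), dtype=np.float32)
        local = token_model.conv_stem(x)
        assert local.shape == (2, 6, 2, 3)

    def test_zero_input_zero_bias_gives_zero_features(self):
        cfg = scale_config(conv_stem_activations="none")
        m = HybridSkinFormer(cfg, seed=0)
        for conv in m.convs:
            conv.bias.value[...] = 0
        local = m.conv_stem(np.zeros((1, 5, 64, 96), dtype=np.float32))
        np.testing.assert_allclose(local, 0.0, atol=1e-7)

    def test_batch_independence(self, token_model, rng):
        x = rng.random((4, 5, 112, 160), dtype=np.float32)
        full = token_model.forward(x)
        single = token_model.forward(x[:1])
        np.testing.assert_allclose(full[0], single[0], atol=1e-5)

    def test_identical_inputs_identical_rows(self, token_model, rng):
        one = rng.random((1, 5, 112, 160), dtype=np.float32)
        x = np.repeat(one, 3, axis=0)
        p = token_model.forward(x)
        np.testing.assert_allclose(p[0], p[1], atol=1e-7)
        np.testing.assert_allclose(p[0], p[2], atol=1e-7)

    def test_probability_rows_sum_to_one(self, token_model, rng):
        p = token_model.forward(rng.random((3, 5, 112, 160), dtype=np.float32))
        assert p.shape == (3, 4)
        assert (p > 0).all() and (p < 1).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_test_scale_forward_contract(self, rng):
        m = HybridSkinFormer(scale_config(), seed=1)
        p = m.forward(rng.random((2, 5, 64, 96), dtype=np.float32))
        assert p.shape == (2, 9)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_spatial_size_rejected(self, token_model):
        with pytest.raises(ValueError):
            token_model.forward(np.zeros((1, 5, 64, 96), dtype=np.float32))

    def test_deterministic_given_parameters(self, token_model, rng):
        x = rng.random((2, 5, 112, 160), dtype=np.float32)
        np.testing.assert_array_equal(token_model.forward(x), token_model.forward(x))


class TestTokenLayout:
    def test_context_positions_count(self, token_model, rng):
        z = token_model.flatten_and_embed(rng.random((1, 6, 2, 3), dtype=np.float32))
        assert z.shape == (1, 6, 6)
        assert token_model.context_num == 6

    def test_reference_config_has_693_positions(self):
        cfg = ModelConfig()
        h, w = conv_output_dims(cfg.conv_schedule(), 784, 1216)
        assert h * w == 693

    def test_row_major_layout(self, token_model):
        local = np.zeros((1, 6, 2, 3), dtype=np.float32)
        local[0, :, 1, 2] = 7.0  # spatial (i=1, j=2) -> token 1*3+2 = 5
        pos = token_model.positional.value
        z = token_model.flatten_and_embed(local)
        np.testing.assert_allclose(z[0, 5], 7.0 + pos[5], atol=1e-6)
        np.testing.assert_allclose(z[0, 0], pos[0], atol=1e-6)

    def test_zero_positional_is_pure_flatten_transpose(self, token_model, rng):
        local = rng.random((2, 6, 2, 3), dtype=np.float32)
        saved = token_model.positional.value.copy()
        token_model.positional.value[...] = 0
        try:
            z = token_model.flatten_and_embed(local)
            np.testing.assert_allclose(
                z, local.reshape(2, 6, 6).transpose(0, 2, 1), atol=1e-7
            )
        finally:
            token_model.positional.value[...] = saved


class TestStackProperties:
    def test_all_alpha_one_makes_stack_identity(self, token_model, rng):
        saved = [layer.raw_alpha.value.copy() for layer in token_model.layers]
        x = rng.random((2, 5, 112, 160), dtype=np.float32)
        try:
            for layer in token_model.layers:
                layer.raw_alpha.value[...] = 60.0
            z = token_model.flatten_and_embed(token_model.conv_stem(x))
            out = z
            for layer in token_model.layers:
                out = layer.forward(out)
            np.testing.assert_allclose(out, z, atol=1e-5)
            # end-to-end: probabilities equal head applied directly to tokens
            probs = token_model.forward(x)
            direct = token_model.head(z)
            np.testing.assert_allclose(probs, direct, atol=1e-6)
        finally:
            for layer, s in zip(token_model.layers, saved):
                layer.raw_alpha.value[...] = s

    def test_permutation_covariance(self, token_model, rng):
        """Permuting tokens and positional rows together permutes outputs."""
        layer = token_model.layers[0]
        z = rng.random((1, 6, 6)).astype(np.float32)
        perm = np.random.default_rng(9).permutation(6)
        out = layer.forward(z)
        out_perm = layer.forward(z[:, perm])
        np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-5)

    def test_gradient_reaches_every_parameter_group(self, token_model, rng):
        """Every learnable tensor gets a nonzero gradient somewhere."""
        from skinformer.nn import efloss_grad, make_loss

        x = rng.random((4, 5, 112, 160), dtype=np.float32)
        y = np.array([0, 1, 2, 3])
        probs = token_model.forward(x)
        token_model.zero_grad()
        token_model.backward(efloss_grad(probs, y, make_loss("efloss", [4, 3, 2, 1])))
        for name, p in token_model.named_parameters():
            assert np.abs(p.grad).max() > 0, f"dead gradient in {name}"


class TestParameterCensus:
    def test_single_linear_layer(self, rng):
        assert Linear(7, 5, rng).num_parameters() == 7 * 5 + 5

    def test_star_prelu_has_three_scalars(self):
        from skinformer.nn import StarPRelu

        assert StarPRelu().num_parameters() == 3

    def test_reference_configuration_census(self):
        m = HybridSkinFormer(ModelConfig(), seed=0)
        rep = count_parameters(m)
        comp = rep["components"]
        # conv weights follow out*in*k*k + out exactly
        assert comp["conv_stem.conv1"] == 30 * 5 * 36 + 30
        assert comp["conv_stem.conv2"] == 90 * 30 * 36 + 90
        assert comp["conv_stem.conv3"] == 180 * 90 * 81 + 180
        assert comp["positional_encoding"] == 693 * 180
        assert rep["total"] == sum(comp.values())
        # the third conv alone exceeds 1.3 M scalars, so the honest total is
        # far above any sub-megabyte census of this architecture
        assert comp["conv_stem.conv3"] > 1_300_000
        assert rep["total_k"] > 310.599
        report = format_parameter_report(m)
        assert "conv_stem.conv3" in report and "total" in report

    def test_census_matches_sum_of_parts(self):
        m = HybridSkinFormer(scale_config(), seed=0)
        assert count_parameters(m)["total"] == m.num_parameters()
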