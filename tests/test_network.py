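"""Exactness checks of the four-block model against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from basisimpute import (
    ConfigurationError,
    DecompositionNetwork,
    DegenerateInputError,
    compute_bias,
)
from conftest import random_window


def loop_masked_column_mean(values, mask):
    T, N = values.shape
    out = np.zeros(N)
    for j in range(N):
        s = c = 0.0
        for t in range(T):
            s += values[t, j] * mask[t, j]
            c += mask[t, j]
        out[j] = s / c if c > 0 else 0.0
    return out


def loop_mlp(layers, x, slope):
    a = x.copy()
    for k, (W, b) in enumerate(layers):
        z = np.zeros(W.shape[1])
        for j in range(W.shape[1]):
            acc = b[j]
            for i in range(W.shape[0]):
                acc += a[i] * W[i, j]
            z[j] = acc
        if k < len(layers) - 1:
            z = np.array([zz if zz >= 0 else slope * zz for zz in z])
        a = z
    return a


class TestComputeBias:
    def test_hand_example(self):
        values = [[1, 4], [3, 9], [5, 4]]
        mask = [[1, 1], [1, 0], [1, 1]]
        np.testing.assert_allclose(compute_bias(values, mask), [3.0, 4.0])

    def test_constant_fully_observed(self):
        values = np.full((5, 3), 7.5)
        np.testing.assert_allclose(compute_bias(values, np.ones((5, 3))), 7.5)

    def test_matches_loop_oracle_on_seeded_window(self, rng):
        values = rng.normal(10, 5, (10, 4))
        mask = (rng.random((10, 4)) > 0.3).astype(float)
        np.testing.assert_allclose(
            compute_bias(values, mask), loop_masked_column_mean(values, mask),
            atol=1e-12,
        )

    @given(seed=st.integers(0, 10_000))
    def test_equals_brute_force_for_random_windows(self, seed):
        gen = np.random.default_rng(seed)
        values, mask = random_window(gen, T=8, N=5, missing=gen.uniform(0, 0.8))
        np.testing.assert_allclose(
            compute_bias(values, mask), loop_masked_column_mean(values, mask),
            atol=1e-12,
        )

    def test_all_missing_window_is_an_error(self):
        with pytest.raises(DegenerateInputError, match="window 0"):
            compute_bias(np.zeros((4, 2)), np.zeros((4, 2)))

    def test_all_missing_station_falls_back_to_zero(self):
        values = np.full((4, 2), 9.0)
        mask = np.column_stack([np.ones(4), np.zeros(4)])
        np.testing.assert_allclose(compute_bias(values, mask), [9.0, 0.0])


class TestEncoder:
    def test_each_block_owns_an_independent_five_layer_encoder(self):
        net = DecompositionNetwork(n_stations=2, window_length=4, hidden_dim=3,
                                   random_state=0)
        assert set(net.encoders) == {"slope", "season", "residual"}
        for layers in net.encoders.values():
            assert len(layers) == 5
        ids = {id(layers[0][0]) for layers in net.encoders.values()}
        assert len(ids) == 3  # no weight sharing between blocks
        assert net.encoders["slope"][-1][0].shape[1] == 1
        assert net.encoders["season"][-1][0].shape[1] == 8
        assert net.encoders["residual"][-1][0].shape[1] == net.residual_dim

    def test_zero_network_maps_anything_to_zero(self):
        net = DecompositionNetwork(n_stations=2, window_length=4, hidden_dim=3,
                                   random_state=0)
        for layers in net.encoders.values():
            for W, b in layers:
                W[...] = 0.0
        x = np.arange(8.0).reshape(4, 2)
        for block in ("slope", "season", "residual"):
            assert np.all(net.encode_coefficients(x, block) == 0.0)

    def test_scalar_path_composes_affine_maps(self):
        # 1x1 window, width-1 layers: the encoder is five chained scalar
        # affine maps with the leaky rectifier between them
        net = DecompositionNetwork(n_stations=1, window_length=2, hidden_dim=1,
                                   season_dim=1, residual_dim=1, random_state=0)
        ws = [1.5, -2.0, 0.5, 3.0, -1.0]
        bs = [0.1, 0.2, -0.3, 0.4, 0.5]
        for (W, b), w_val, b_val in zip(net.encoders["slope"], ws, bs):
            W[...] = w_val
            b[...] = b_val
        x = np.array([[0.7], [0.0]])
        a = np.array([0.7, 0.0])
        for k, (w_val, b_val) in enumerate(zip(ws, bs)):
            z = a @ np.full((a.size, 1), w_val) + b_val
            a = np.where(z >= 0, z, 0.2 * z).ravel() if k < 4 else z.ravel()
        got = net.encode_coefficients(x, "slope")
        np.testing.assert_allclose(got, a, atol=1e-12)

    def test_matches_loop_oracle_with_random_weights(self, small_network, rng):
        x = rng.normal(0, 1, (6, 3))
        for block in ("slope", "season", "residual"):
            got = small_network.encode_coefficients(x, block)
            want = loop_mlp(small_network.encoders[block], x.ravel(), 0.2)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_shape_mismatch_is_configuration_error(self, small_network):
        with pytest.raises(ConfigurationError):
            small_network.encode_coefficients(np.zeros((5, 3)), "slope")


class TestComponents:
    def test_slope_zero_coefficient(self, small_network):
        assert np.all(small_network.slope_component(0.0) == 0.0)

    def test_slope_known_values(self):
        net = DecompositionNetwork(n_stations=1, window_length=4, hidden_dim=2,
                                   random_state=0)
        np.testing.assert_allclose(net.slope_component(2.0), [-1.0, -0.5, 0.0, 0.5])

    def test_slope_is_linear_in_theta(self, small_network, rng):
        theta = rng.normal()
        a = rng.normal()
        np.testing.assert_array_equal(
            small_network.slope_component(a * theta),
            a * small_network.slope_component(theta),
        )

    def test_season_zero_vector(self, small_network):
        assert np.all(small_network.seasonality_component(np.zeros(8)) == 0.0)

    def test_season_first_cosine_at_origin(self):
        net = DecompositionNetwork(n_stations=1, window_length=6, hidden_dim=2,
                                   random_state=0)
        theta = np.zeros(8)
        theta[1] = 3.25  # b_1, the first cosine coefficient
        out = net.seasonality_component(theta)
        assert out[3] == pytest.approx(3.25)  # v_raw = 0 at index T//2

    def test_season_matches_four_term_loop(self, small_network, rng):
        theta = rng.normal(0, 2, 8)
        v = small_network.basis.v_norm
        want = np.zeros(len(v))
        for i in range(1, 5):
            want += theta[2 * i - 2] * np.sin(2 * np.pi * i * v)
            want += theta[2 * i - 1] * np.cos(2 * np.pi * i * v)
        np.testing.assert_allclose(
            small_network.seasonality_component(theta), want, atol=1e-9
        )

    def test_season_output_lies_in_basis_span(self, small_network, rng):
        # project back onto the 8 Fourier vectors and re-synthesise
        theta = rng.normal(0, 3, 8)
        out = small_network.seasonality_component(theta)
        F = small_network._F
        coef, *_ = np.linalg.lstsq(F, out, rcond=None)
        assert np.abs(F @ coef - out).max() < 1e-8

    def test_residual_zero_theta_zero_head(self):
        net = DecompositionNetwork(n_stations=3, window_length=6, hidden_dim=4,
                                   residual_dim=5, random_state=0)
        assert np.all(net.residual_component(np.zeros(5)) == 0.0)

    def test_residual_constant_head_offset(self):
        net = DecompositionNetwork(n_stations=3, window_length=6, hidden_dim=4,
                                   residual_dim=5, random_state=0)
        c = np.arange(18.0)
        net.head[1][...] = c
        out = net.residual_component(np.zeros(5))
        np.testing.assert_array_equal(out.ravel(), c)

    def test_residual_matches_plain_loop(self, small_network, rng):
        theta = rng.normal(0, 1, 16)
        u = np.where(theta >= 0, theta, 0.2 * theta)
        W, b = small_network.head
        want = np.zeros(W.shape[1])
        for j in range(W.shape[1]):
            want[j] = b[j] + sum(u[i] * W[i, j] for i in range(W.shape[0]))
        got = small_network.residual_component(theta)
        np.testing.assert_allclose(got.ravel(), want, atol=1e-9)

    def test_residual_head_dimension_mismatch(self, small_network):
        with pytest.raises(ConfigurationError):
            small_network.residual_component(np.zeros(4))


class TestForwardDecompose:
    def test_zero_encoders_reduce_to_masked_mean_imputation(self, rng):
        net = DecompositionNetwork(n_stations=3, window_length=6, hidden_dim=8,
                                   residual_dim=16, random_state=0)
        values, mask = random_window(rng)
        dec = net.forward(values, mask)
        bias = compute_bias(values, mask)
        np.testing.assert_allclose(dec.y_hat, np.broadcast_to(bias, (6, 3)),
                                   atol=1e-12)
        observed = mask == 1
        np.testing.assert_allclose(
            dec.x_final[observed],
            (values - bias[None, :])[observed], atol=1e-12,
        )

    @given(seed=st.integers(0, 10_000))
    def test_decomposition_identity_for_arbitrary_weights(self, seed):
        gen = np.random.default_rng(seed)
        net = DecompositionNetwork(n_stations=3, window_length=6, hidden_dim=8,
                                   residual_dim=16, random_state=seed)
        for p in net.parameters():
            p[...] = gen.normal(0, 0.4, p.shape)
        values, mask = random_window(gen)
        dec = net.forward(values, mask)
        total = (dec.h_bias[None, :] + dec.h_slope[:, None]
                 + dec.h_season[:, None] + dec.h_resid)
        assert np.abs(dec.y_hat - total).max() < 1e-9
        bias_filled = np.where(mask == 1, values, dec.h_bias[None, :])
        assert np.abs(dec.x_final + dec.y_hat - bias_filled).max() < 1e-9

    def test_every_intermediate_matches_straight_line_oracle(self, small_network, rng):
        values, mask = random_window(rng)
        net = small_network
        dec = net.forward(values, mask)

        bias = loop_masked_column_mean(values, mask)
        filled = np.where(mask == 1, values, bias[None, :])
        X1 = filled - bias[None, :]
        th2 = loop_mlp(net.encoders["slope"], X1.ravel(), 0.2)
        h_slope = th2[0] * net.basis.v_norm
        X2 = X1 - h_slope[:, None]
        th3 = loop_mlp(net.encoders["season"], X2.ravel(), 0.2)
        v = net.basis.v_norm
        h_season = np.zeros(len(v))
        for i in range(1, 5):
            h_season += th3[2 * i - 2] * np.sin(2 * np.pi * i * v)
            h_season += th3[2 * i - 1] * np.cos(2 * np.pi * i * v)
        X3 = X2 - h_season[:, None]
        th4 = loop_mlp(net.encoders["residual"], X3.ravel(), 0.2)
        u = np.where(th4 >= 0, th4, 0.2 * th4)
        W, b = net.head
        h_resid = (u @ W + b).reshape(values.shape)
        X4 = X3 - h_resid

        np.testing.assert_allclose(dec.h_bias, bias, atol=1e-9)
        np.testing.assert_allclose(dec.h_slope, h_slope, atol=1e-9)
        np.testing.assert_allclose(dec.h_season, h_season, atol=1e-9)
        np.testing.assert_allclose(dec.h_resid, h_resid, atol=1e-9)
        np.testing.assert_allclose(dec.x_final, X4, atol=1e-9)
        np.testing.assert_allclose(
            dec.y_hat, bias[None, :] + h_slope[:, None] + h_season[:, None] + h_resid,
            atol=1e-9,
        )

    def test_wrong_window_shape_rejected(self, small_network):
        with pytest.raises(ConfigurationError):
            small_network.forward(np.zeros((5, 3)), np.ones((5, 3)))


class TestGradients:
    def test_backprop_matches_central_differences(self, small_network, rng):
        net = small_network
        values = rng.normal(5, 2, (3, 6, 3))
        mask = (rng.random((3, 6, 3)) > 0.3).astype(float)
        target = rng.normal(5, 2, (3, 6, 3))
        _, grads = net.loss_and_gradients(values, mask, target, mask)
        params = net.parameters()
        eps = 1e-6
        gen = np.random.default_rng(5)
        for pi in range(len(params)):
            p = params[pi]
            flat = p.reshape(-1)
            for idx in gen.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = net.loss_and_gradients(values, mask, target, mask)
                flat[idx] = orig - eps
                lm, _ = net.loss_and_gradients(values, mask, target, mask)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[pi].reshape(-1)[idx]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num), abs(ana))


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_outputs(self, small_network, rng, tmp_path):
        path = tmp_path / "model.npz"
        small_network.save(path)
        loaded = DecompositionNetwork.load(path)
        values, mask = random_window(rng)
        d1 = small_network.forward(values, mask)
        d2 = loaded.forward(values, mask)
        np.testing.assert_array_equal(d1.y_hat, d2.y_hat)
        assert loaded.hidden_dim == small_network.hidden_dim
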