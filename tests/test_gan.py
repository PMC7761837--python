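"""Cell equations, generator/discriminator mechanics, and training contracts."""

import numpy as np
import pytest

import synsiggan as sg
from synsiggan.gan import (BiGridLstmParams, DiscriminatorParams, GanConfig,
                           GridBlockParams, GridDimParams, LstmGates,
                           LstmParams, _disc_layer_dims)


def sigmoid_scalar(v):
    return 1.0 / (1.0 + np.exp(-v))


def lstm_oracle(x, h_prev, c_prev, p):
    """Scalar-loop transcription of the six LSTM update lines."""
    hidden = p.g_I.size

    def gate(A, B, D, g, c_ref, squash):
        out = np.empty(hidden)
        for j in range(hidden):
            acc = g[j]
            for k in range(len(x)):
                acc += x[k] * A[k, j]
            for k in range(hidden):
                acc += h_prev[k] * B[k, j]
            if D is not None:
                for k in range(hidden):
                    acc += c_ref[k] * D[k, j]
            out[j] = squash(acc)
        return out

    i = gate(p.A_I, p.B_I, p.D_I, p.g_I, c_prev, sigmoid_scalar)
    f = gate(p.A_F, p.B_F, p.D_F, p.g_F, c_prev, sigmoid_scalar)
    c_hat = gate(p.A_C, p.B_C, None, p.g_C, None, np.tanh)
    c = f * c_prev + i * c_hat
    o = gate(p.A_O, p.B_O, p.D_O, p.g_O, c, sigmoid_scalar)
    gated = o * np.tanh(c)
    h = np.array([sum(gated[k] * p.A_proj[k, j] for k in range(hidden))
                  for j in range(p.A_proj.shape[1])])
    return i, f, c_hat, c, o, h


def dim_block_oracle(x, h_rec, c_prev, p: GridDimParams):
    """Scalar-loop transcription of one grid-dimension block."""
    lp = LstmParams(p.A_I.copy(), p.B_I.copy(), p.D_I.copy(), None,
                    p.A_F.copy(), p.B_F.copy(), p.D_F.copy(), None,
                    p.A_C.copy(), p.B_C.copy(), None,
                    p.A_O.copy(), p.B_O.copy(), p.D_O.copy(), None,
                    p.proj.copy())
    h = p.hidden
    lp.g_I, lp.g_F, lp.g_C, lp.g_O = (p.g[:h].copy(), p.g[h:2 * h].copy(),
                                      p.g[2 * h:3 * h].copy(), p.g[3 * h:].copy())
    i, f, c_hat, c, o, hout = lstm_oracle(x, h_rec, c_prev, lp)
    return hout, c


class TestLstmStep:
    def test_zero_parameters_half_gates_zero_state(self):
        p = LstmParams.zeros(2, 3)
        out = sg.lstm_step(np.ones(2), LstmGates.initial(3), p)
        np.testing.assert_allclose(out.I, 0.5)
        np.testing.assert_allclose(out.F, 0.5)
        np.testing.assert_allclose(out.O, 0.5)
        assert np.all(out.C == 0) and np.all(out.C_hat == 0) and np.all(out.H == 0)

    def test_saturated_gates_carry_memory(self, rng):
        p = LstmParams.zeros(2, 3)
        p.g_F[:] = 1e3    # forget gate -> 1: keep everything
        p.g_I[:] = -1e3   # input gate -> 0: admit nothing
        prev = LstmGates.initial(3)
        prev.C = rng.standard_normal(3)
        out = sg.lstm_step(rng.standard_normal(2), prev, p)
        np.testing.assert_allclose(out.C, prev.C, atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        p = LstmParams.random(rng, 2, 3)
        x = rng.standard_normal(2)
        prev = LstmGates.initial(3)
        prev.H = rng.standard_normal(3)
        prev.C = rng.standard_normal(3)
        out = sg.lstm_step(x, prev, p)
        i, f, c_hat, c, o, h = lstm_oracle(x, prev.H, prev.C, p)
        np.testing.assert_allclose(out.I, i, atol=1e-12)
        np.testing.assert_allclose(out.F, f, atol=1e-12)
        np.testing.assert_allclose(out.C_hat, c_hat, atol=1e-12)
        np.testing.assert_allclose(out.C, c, atol=1e-12)
        np.testing.assert_allclose(out.O, o, atol=1e-12)
        np.testing.assert_allclose(out.H, h, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        p = LstmParams.random(rng, 2, 3)
        with pytest.raises(ValueError):
            sg.lstm_step(np.ones(5), LstmGates.initial(3), p)

    def test_gate_ranges_over_random_steps(self, rng):
        # moderate weights: gates stay strictly inside the sigmoid range
        p = LstmParams.random(rng, 4, 4, scale=0.3)
        state = LstmGates.initial(4)
        for _ in range(300):
            state = sg.lstm_step(rng.standard_normal(4), state, p)
            assert np.all((state.I > 0) & (state.I < 1))
            assert np.all((state.F > 0) & (state.F < 1))
            assert np.all((state.O > 0) & (state.O < 1))
            assert np.all(np.isfinite(state.C))
        # large weights saturate to the closed interval in float arithmetic
        # but the cell state must stay finite
        p = LstmParams.random(rng, 4, 4, scale=2.0)
        state = LstmGates.initial(4)
        for _ in range(300):
            state = sg.lstm_step(rng.standard_normal(4), state, p)
            for gate in (state.I, state.F, state.O):
                assert np.all((gate >= 0) & (gate <= 1))
            assert np.all(np.isfinite(state.C))


class TestGridStep:
    def test_zero_parameters_propagate_zero(self):
        blk = GridBlockParams.zeros(3, 4)
        (h_t, c_t), (h_d, c_d) = sg.grid_step(
            np.ones(3), np.zeros(4), np.zeros(4), np.zeros(4), blk)
        for arr in (h_t, c_t, h_d, c_d):
            assert np.all(arr == 0)

    def test_depth_block_reduces_to_lstm_without_peepholes(self, rng):
        blk = GridBlockParams.glorot(rng, 3, 4)
        for name in ("D_I", "D_F", "D_O"):
            getattr(blk.depth, name)[:] = 0.0
        x = rng.standard_normal(3)
        h_rec = rng.standard_normal(4)
        c_dep = rng.standard_normal(4)
        _, (h_d, c_d) = sg.grid_step(x, h_rec, np.zeros(4), c_dep, blk)

        lp = LstmParams.zeros(3, 4)
        for gate, k in zip("IFCO", range(4)):
            getattr(lp, f"A_{gate}")[...] = blk.depth.W_x[:, k * 4:(k + 1) * 4]
            getattr(lp, f"B_{gate}")[...] = blk.depth.W_h[:, k * 4:(k + 1) * 4]
            getattr(lp, f"g_{gate}")[...] = blk.depth.g[k * 4:(k + 1) * 4]
        lp.A_proj[...] = blk.depth.proj
        prev = LstmGates.initial(4)
        prev.H, prev.C = h_rec, c_dep
        ref = sg.lstm_step(x, prev, lp)
        np.testing.assert_allclose(h_d, ref.H, atol=1e-12)
        np.testing.assert_allclose(c_d, ref.C, atol=1e-12)

    def test_both_blocks_match_scalar_loop_oracle(self, rng):
        blk = GridBlockParams.glorot(rng, 2, 3)
        for dim in (blk.time, blk.depth):
            for name in ("D_I", "D_F", "D_O"):
                getattr(dim, name)[...] = 0.3 * rng.standard_normal((3, 3))
        x = rng.standard_normal(2)
        h_tm, c_tm = rng.standard_normal(3), rng.standard_normal(3)
        c_dep = rng.standard_normal(3)
        (h_t, c_t), (h_d, c_d) = sg.grid_step(x, h_tm, c_tm, c_dep, blk)
        ref_ht, ref_ct = dim_block_oracle(x, h_tm, c_tm, blk.time)
        ref_hd, ref_cd = dim_block_oracle(x, h_tm, c_dep, blk.depth)
        np.testing.assert_allclose(h_t, ref_ht, atol=1e-12)
        np.testing.assert_allclose(c_t, ref_ct, atol=1e-12)
        np.testing.assert_allclose(h_d, ref_hd, atol=1e-12)
        np.testing.assert_allclose(c_d, ref_cd, atol=1e-12)


class TestGenerator:
    def test_zero_weights_zero_output(self, tiny_gan_config):
        params = BiGridLstmParams.init(tiny_gan_config)
        z = np.random.default_rng(0).standard_normal(
            (tiny_gan_config.segment_length, tiny_gan_config.noise_dim))
        assert np.all(sg.bigridlstm_generate(z, params, tiny_gan_config) == 0)

    def test_deterministic_given_noise(self, tiny_gan_config, rng):
        params = BiGridLstmParams.init(tiny_gan_config, rng)
        z = rng.standard_normal((tiny_gan_config.segment_length,
                                 tiny_gan_config.noise_dim))
        a = sg.bigridlstm_generate(z, params, tiny_gan_config)
        b = sg.bigridlstm_generate(z, params, tiny_gan_config)
        assert np.array_equal(a, b)
        assert a.shape == (tiny_gan_config.segment_length,)

    def test_direction_swap_time_reversal_symmetry(self, tiny_gan_config, rng):
        params = BiGridLstmParams.init(tiny_gan_config, rng)
        z = rng.standard_normal((tiny_gan_config.segment_length,
                                 tiny_gan_config.noise_dim))
        y = sg.bigridlstm_generate(z, params, tiny_gan_config)
        y_rev = sg.bigridlstm_generate(z[::-1], params.direction_swapped(),
                                       tiny_gan_config)
        np.testing.assert_allclose(y_rev[::-1], y, atol=1e-10)

    def test_noise_shape_validated(self, tiny_gan_config, rng):
        params = BiGridLstmParams.init(tiny_gan_config, rng)
        with pytest.raises(ValueError):
            sg.bigridlstm_generate(np.zeros((5, 3)), params, tiny_gan_config)


class TestDiscriminator:
    @pytest.mark.parametrize("T,H,P,expected", [
        (128, 5, 3, 42), (64, 5, 3, 20), (32, 5, 1, 28), (16, 3, 2, 7)])
    def test_first_conv_length_law(self, T, H, P, expected):
        cfg = GanConfig(segment_length=T, kernel_sizes=(H, 3), stride=P,
                        pool_sizes=(1, 1))
        assert _disc_layer_dims(cfg)[0] == (T - H) // P + 1 == expected

    def test_softmax_outputs_sum_to_one(self, tiny_gan_config, rng):
        params = DiscriminatorParams.init(tiny_gan_config, rng)
        x = rng.standard_normal(tiny_gan_config.segment_length)
        p_real, p_fake = sg.discriminator_forward(x, params, tiny_gan_config)
        assert p_real + p_fake == pytest.approx(1.0, abs=1e-12)
        batch = rng.standard_normal((5, tiny_gan_config.segment_length))
        probs = sg.discriminator_forward(batch, params, tiny_gan_config)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_weights_give_half_half(self, tiny_gan_config, rng):
        params = DiscriminatorParams.init(tiny_gan_config)
        x = rng.standard_normal(tiny_gan_config.segment_length)
        assert sg.discriminator_forward(x, params, tiny_gan_config) == (0.5, 0.5)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            GanConfig(segment_length=4, kernel_sizes=(5, 3))


class TestTraining:
    def test_one_epoch_smoke(self, sinusoid_segments):
        cfg = sg.GanConfig(segment_length=64, hidden_size=8, epochs=1, seed=0,
                           batch_size=32)
        model, trace = sg.gan_train(sinusoid_segments[:8], cfg)
        assert len(trace.g_loss) == len(trace.d_loss) == 1
        assert np.isfinite(trace.g_loss[0]) and np.isfinite(trace.d_loss[0])

    def test_same_seed_identical_traces(self, sinusoid_segments):
        cfg = sg.GanConfig(segment_length=64, hidden_size=6, epochs=2, seed=5)
        _, t1 = sg.gan_train(sinusoid_segments[:16], cfg)
        _, t2 = sg.gan_train(sinusoid_segments[:16], cfg)
        assert t1.g_loss == t2.g_loss and t1.d_loss == t2.d_loss

    def test_empty_input_rejected(self, tiny_gan_config):
        with pytest.raises(ValueError):
            sg.gan_train(np.empty((0, 32)), tiny_gan_config)

    def test_count_parity_and_determinism(self, sinusoid_segments):
        cfg = sg.GanConfig(segment_length=64, hidden_size=6, epochs=1, seed=1)
        model, _ = sg.gan_train(sinusoid_segments[:8], cfg)
        assert sg.generate_synthetic(model, 0) == []
        batch = sg.generate_synthetic(model, 37, seed=9)
        assert len(batch) == 37
        assert all(b.shape == (64,) for b in batch)
        again = sg.generate_synthetic(model, 37, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(batch, again))
        with pytest.raises(ValueError):
            sg.generate_synthetic(model, -1)

    def test_checkpoint_round_trip(self, tmp_path, sinusoid_segments):
        cfg = sg.GanConfig(segment_length=64, hidden_size=6, epochs=1, seed=2)
        model, _ = sg.gan_train(sinusoid_segments[:8], cfg)
        path = tmp_path / "model.npz"
        sg.save_model(model, path)
        loaded = sg.load_model(path)
        a = sg.generate_synthetic(model, 3, seed=4)
        b = sg.generate_synthetic(loaded, 3, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert loaded.config == model.config


class TestGradients:
    def test_training_losses_match_finite_differences(self, rng):
        """Spot-check the end-to-end generator gradient numerically."""
        from synsiggan._autodiff import data_of, log_softmax, mean_of_col, neg
        from synsiggan.gan import _disc_logits, _generator_forward
        cfg = GanConfig(segment_length=16, hidden_size=3, noise_dim=2,
                        conv_filters=(2, 2), kernel_sizes=(5, 3), stride=3,
                        pool_sizes=(1, 1))
        gen = BiGridLstmParams.init(cfg, rng).as_tensors()
        disc = DiscriminatorParams.init(cfg, rng).as_tensors()
        z = rng.standard_normal((3, 16, 2))

        def loss():
            lsm = log_softmax(_disc_logits(_generator_forward(z, gen, cfg),
                                           disc, cfg))
            return neg(mean_of_col(lsm, 0))

        node = loss()
        for p in gen.leaves() + disc.leaves():
            p.zero_grad()
        node.backward()
        eps = 1e-5
        for p in list(gen.leaves())[:6] + list(disc.leaves()):
            flat = p.data.ravel()
            i = int(rng.integers(flat.size))
            old = flat[i]
            flat[i] = old + eps
            up = float(data_of(loss()))
            flat[i] = old - eps
            dn = float(data_of(loss()))
            flat[i] = old
            numeric = (up - dn) / (2 * eps)
            analytic = 0.0 if p.grad is None else p.grad.ravel()[i]
            assert numeric == pytest.approx(analytic, abs=1e-6)
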