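"""SPS-backed layers: hand-computed examples, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mode import autodiff as ad
from mode.autodiff import Tensor
from mode.blocks import (FFN, AttentionBlock, BiLSTM, Conv1D, Linear,
                         LSTMCellParams, LSTMLayer, LSTMState, attention,
                         generate_group, lstm_cell_step, reverse_padded)
from mode.sps import Template


def make_rng():
    return np.random.default_rng(0)


class TestLinear:
    def test_identity_weight_zero_bias_is_identity(self, rng):
        lin = Linear("l", 3, 3, make_rng())
        lin.weight.tensor.data[:] = np.eye(3)
        x = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(lin(Tensor(x)).data, x)

    def test_hand_example(self):
        lin = Linear("l", 2, 2, make_rng())
        lin.weight.tensor.data[:] = [[1.0, 0.0], [0.0, 2.0]]
        lin.bias.data[:] = [0.5, 0.5]
        out = lin(Tensor(np.array([[1.0, 2.0]])))
        np.testing.assert_allclose(out.data, [[1.5, 4.5]], rtol=1e-15)

    def test_templated_delta_kernel_equals_dense_slice(self, rng):
        """A one-hot kernel makes the templated linear equal a dense linear
        whose weight is the selected template slice."""
        tpl = Template.create(4, 6, 6, seed=2)
        lin = Linear("t", 6, 6, make_rng(), template=tpl)
        k = lin.weight.binding.kernel
        k.activation = "identity"
        k.values.data[:] = 0.0
        k.values.data[1, 0, 0, 0] = 1.0
        lin.bias.data[:] = 0.0
        x = rng.standard_normal((3, 6))
        want = x @ tpl.values.data[1]
        np.testing.assert_allclose(lin(Tensor(x)).data, want, rtol=1e-12)

    def test_dimension_mismatch_raises(self):
        lin = Linear("l", 3, 2, make_rng())
        with pytest.raises(ValueError, match="last dim"):
            lin(Tensor(np.zeros((2, 4))))


class TestConv1D:
    def test_zero_kernel_outputs_bias(self, rng):
        conv = Conv1D("c", 3, 3, make_rng())
        conv.weight.tensor.data[:] = 0.0
        conv.bias.data[:] = [1.0, -2.0, 0.5]
        out = conv(Tensor(rng.standard_normal((2, 5, 3))))
        np.testing.assert_allclose(out.data, np.broadcast_to(
            [1.0, -2.0, 0.5], (2, 5, 3)), rtol=1e-15)

    def test_width_one_kernel_equals_linear(self, rng):
        conv = Conv1D("c", 4, 1, make_rng())
        W = conv.weight.tensor.data[:, :, 0]
        x = rng.standard_normal((2, 6, 4))
        want = x @ W + conv.bias.data
        np.testing.assert_allclose(conv(Tensor(x)).data, want, rtol=1e-12)

    def test_impulse_reveals_kernel(self, rng):
        conv = Conv1D("c", 2, 3, make_rng())
        conv.bias.data[:] = 0.0
        x = np.zeros((1, 7, 2))
        x[0, 3, 0] = 1.0  # impulse in channel 0 at the center
        out = conv(Tensor(x)).data[0]
        W = conv.weight.tensor.data  # (n_in, n_out, k)
        # output at position 3+d picks up W[0, :, k-1-d+offset]; same padding
        for d, kk in [(-1, 2), (0, 1), (1, 0)]:
            np.testing.assert_allclose(out[3 + d], W[0, :, kk], rtol=1e-12)

    def test_length_preserved(self, rng):
        conv = Conv1D("c", 3, 3, make_rng())
        out = conv(Tensor(rng.standard_normal((2, 9, 3))))
        assert out.shape == (2, 9, 3)


class TestLSTM:
    def test_zero_everything_gives_zero_state(self):
        params = LSTMCellParams("z", 3, make_rng())
        for g in params.GATES:
            params.W[g].tensor.data[:] = 0.0
            params.U[g].tensor.data[:] = 0.0
        zero = Tensor(np.zeros((1, 3)))
        new = lstm_cell_step(LSTMState(zero, zero),
                             Tensor(np.ones((1, 3))), params)
        np.testing.assert_array_equal(new.c.data, 0.0)
        np.testing.assert_array_equal(new.h.data, 0.0)

    def test_scalar_hand_example(self):
        """n=1, unit weights, zero bias, x=1, prior state 0:
        f=i=o=sigma(1), d=tanh(1), c=d*i, h=o*tanh(c)."""
        params = LSTMCellParams("s", 1, make_rng())
        for g in params.GATES:
            params.W[g].tensor.data[:] = 1.0
            params.U[g].tensor.data[:] = 1.0
        zero = Tensor(np.zeros((1, 1)))
        new = lstm_cell_step(LSTMState(zero, zero), Tensor(np.ones((1, 1))),
                             params)
        sig1, tanh1 = 1 / (1 + np.exp(-1)), np.tanh(1.0)
        np.testing.assert_allclose(new.c.data, tanh1 * sig1, rtol=1e-12)
        np.testing.assert_allclose(new.c.data.item(), 0.5569, atol=2.5e-4)
        np.testing.assert_allclose(new.h.data, sig1 * np.tanh(tanh1 * sig1),
                                   rtol=1e-12)
        np.testing.assert_allclose(new.h.data.item(), 0.3694, atol=2.5e-4)

    def test_cell_state_decays_under_zero_input(self, rng):
        """With zero inputs the forget gate sigma(0)=0.5 < 1 shrinks |c|."""
        params = LSTMCellParams("d", 4, make_rng())
        for g in params.GATES:
            params.W[g].tensor.data[:] = 0.0
            params.U[g].tensor.data[:] = 0.0
        state = LSTMState(Tensor(np.zeros((1, 4))),
                          Tensor(rng.standard_normal((1, 4))))
        mags = [np.abs(state.c.data).max()]
        for _ in range(10):
            state = lstm_cell_step(state, Tensor(np.zeros((1, 4))), params)
            mags.append(np.abs(state.c.data).max())
        assert all(b < a for a, b in zip(mags, mags[1:]))

    def test_hidden_state_bounded(self, rng):
        """|h| < 1 always: h = sigmoid(.) * tanh(.)."""
        layer = LSTMLayer("b", 5, make_rng())
        x = Tensor(rng.standard_normal((3, 20, 5)) * 10)
        out, state = layer(x)
        assert np.abs(out.data).max() < 1.0
        assert np.abs(state.h.data).max() < 1.0

    def test_non_finite_state_rejected(self):
        params = LSTMCellParams("n", 2, make_rng())
        bad = LSTMState(Tensor(np.full((1, 2), np.nan)), Tensor(np.zeros((1, 2))))
        with pytest.raises(FloatingPointError):
            lstm_cell_step(bad, Tensor(np.zeros((1, 2))), params)

    def test_masked_positions_freeze_state(self, rng):
        layer = LSTMLayer("m", 3, make_rng())
        x = rng.standard_normal((2, 6, 3))
        mask = np.array([[1, 1, 1, 0, 0, 0], [1, 1, 1, 1, 1, 1]], dtype=bool)
        _, state = layer(Tensor(x), mask=mask)
        _, state3 = layer(Tensor(x[:, :3]), mask=mask[:, :3])
        np.testing.assert_allclose(state.h.data[0], state3.h.data[0], rtol=1e-12)


class TestBiLSTM:
    def test_channel_dim_doubles(self, rng):
        bi = BiLSTM("b", 4, make_rng())
        x = Tensor(rng.standard_normal((2, 7, 4)))
        out, _, _ = bi(x, np.ones((2, 7), dtype=bool))
        assert out.shape == (2, 7, 8)

    def test_length_one_directions_agree_up_to_parameters(self, rng):
        """On a length-1 input both directions see the same single token."""
        bi = BiLSTM("b1", 3, make_rng())
        # tie the two parameter sets
        for g in bi.fwd.params.GATES:
            bi.bwd.params.W[g].tensor.data[:] = bi.fwd.params.W[g].tensor.data
            bi.bwd.params.U[g].tensor.data[:] = bi.fwd.params.U[g].tensor.data
        x = Tensor(rng.standard_normal((2, 1, 3)))
        out, st_f, st_b = bi(x, np.ones((2, 1), dtype=bool))
        np.testing.assert_allclose(st_f.h.data, st_b.h.data, rtol=1e-12)

    def test_palindrome_symmetry_with_tied_parameters(self, rng):
        bi = BiLSTM("p", 3, make_rng())
        for g in bi.fwd.params.GATES:
            bi.bwd.params.W[g].tensor.data[:] = bi.fwd.params.W[g].tensor.data
            bi.bwd.params.U[g].tensor.data[:] = bi.fwd.params.U[g].tensor.data
        half = rng.standard_normal((1, 3, 3))
        pal = np.concatenate([half, half[:, ::-1]], axis=1)  # palindrome
        out, _, _ = bi(Tensor(pal), np.ones((1, 6), dtype=bool))
        n = 3
        reversed_swapped = np.concatenate(
            [out.data[:, ::-1, n:], out.data[:, ::-1, :n]], axis=-1)
        np.testing.assert_allclose(out.data, reversed_swapped, rtol=1e-10)

    def test_reverse_padded_reverses_within_lengths(self):
        ids = np.array([[1, 2, 3, 0, 0], [4, 5, 6, 7, 8]])
        mask = ids != 0
        rev = reverse_padded(ids, mask)
        np.testing.assert_array_equal(rev, [[3, 2, 1, 0, 0], [8, 7, 6, 5, 4]])


class TestAttention:
    def test_single_key_returns_value(self, rng):
        Q = Tensor(rng.standard_normal((2, 4, 3)))
        K = Tensor(rng.standard_normal((2, 1, 3)))
        V = Tensor(rng.standard_normal((2, 1, 3)))
        out = attention(Q, K, V)
        np.testing.assert_allclose(out.data,
                                   np.broadcast_to(V.data, (2, 4, 3)),
                                   rtol=1e-12)

    def test_causal_first_position_sees_only_first_value(self, rng):
        x = Tensor(rng.standard_normal((1, 5, 4)))
        out = attention(x, x, x, causal=True)
        np.testing.assert_allclose(out.data[0, 0], x.data[0, 0], rtol=1e-12)

    def test_equal_scores_give_column_mean(self):
        T, n = 4, 3
        Q = Tensor(np.zeros((1, T, n)))
        K = Tensor(np.zeros((1, T, n)))
        V = Tensor(np.arange(T * n, dtype=float).reshape(1, T, n))
        out = attention(Q, K, V)
        np.testing.assert_allclose(out.data,
                                   np.broadcast_to(V.data.mean(axis=1,
                                                               keepdims=True),
                                                   (1, T, n)), rtol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 16), st.booleans())
    def test_rows_are_stochastic(self, seed, causal):
        rng = np.random.default_rng(seed)
        Tq = int(rng.integers(1, 6))
        Tk = Tq if causal else int(rng.integers(1, 6))
        Q = Tensor(rng.standard_normal((2, Tq, 4)) * 3)
        K = Tensor(rng.standard_normal((2, Tk, 4)) * 3)
        V = Tensor(rng.standard_normal((2, Tk, 4)))
        key_mask = np.ones((2, Tk), dtype=bool)
        key_mask[:, Tk - 1:] = rng.integers(0, 2) or Tk == 1
        _, w = attention(Q, K, V, causal=causal, key_mask=key_mask,
                         return_weights=True)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_causality_future_perturbation_invisible(self, rng):
        x = rng.standard_normal((1, 6, 4))
        block = AttentionBlock("a", 4, make_rng())
        out1 = block(Tensor(x), Tensor(x), causal=True).data
        x2 = x.copy()
        x2[0, 4:] += 5.0  # perturb positions 4,5
        out2 = block(Tensor(x2), Tensor(x2), causal=True).data
        np.testing.assert_allclose(out1[0, :4], out2[0, :4], rtol=1e-10)
        assert not np.allclose(out1[0, 4:], out2[0, 4:])

    def test_length_mismatch_rejected(self, rng):
        Q = Tensor(rng.standard_normal((1, 3, 4)))
        K = Tensor(rng.standard_normal((1, 2, 4)))
        V = Tensor(rng.standard_normal((1, 3, 4)))
        with pytest.raises(ValueError, match="lengths"):
            attention(Q, K, V)


class TestFFN:
    def test_zero_weights_give_constant_bias(self, rng):
        ffn = FFN("f", 3, make_rng())
        ffn.inner.weight.tensor.data[:] = 0.0
        ffn.outer.weight.tensor.data[:] = 0.0
        ffn.outer.bias.data[:] = [1.0, 2.0, 3.0]
        out = ffn(Tensor(rng.standard_normal((2, 4, 3))))
        np.testing.assert_allclose(out.data, np.broadcast_to(
            [1.0, 2.0, 3.0], (2, 4, 3)), rtol=1e-15)

    def test_identity_composition_on_nonnegative_input(self, rng):
        ffn = FFN("i", 3, make_rng())
        ffn.inner.weight.tensor.data[:] = np.eye(3)
        ffn.inner.bias.data[:] = 0.0
        ffn.outer.weight.tensor.data[:] = np.eye(3)
        ffn.outer.bias.data[:] = 0.0
        x = np.abs(rng.standard_normal((2, 3)))
        np.testing.assert_array_equal(ffn(Tensor(x)).data, x)

    def test_matches_chained_linears_oracle(self, rng):
        ffn = FFN("o", 4, make_rng())
        x = Tensor(rng.standard_normal((2, 5, 4)))
        want = ffn.outer(ffn.inner(x).relu()).data
        np.testing.assert_array_equal(ffn(x).data, want)


class TestBatchedGeneration:
    def test_group_generation_matches_individual(self, rng):
        """The batched carve used in model forwards must agree with
        generating each module's weight on its own."""
        tpl = Template.create(3, 12, 12, seed=5)
        lins = [Linear(f"g{i}", 8, 8, make_rng(), template=tpl)
                for i in range(3)]
        conv = Conv1D("gc", 8, 3, make_rng(), template=tpl)
        singles = [w.get().data.copy()
                   for w in [l.weight for l in lins] + [conv.weight]]
        generate_group(tpl, [l.weight for l in lins] + [conv.weight])
        for single, mod in zip(singles, [l.weight for l in lins] + [conv.weight]):
            np.testing.assert_allclose(mod._cached.data, single, rtol=1e-9,
                                       atol=1e-12)
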