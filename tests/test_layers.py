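import numpy as np
import pytest

from clpmi.layers import (
    BatchNorm,
    LstmParams,
    bilstm_forward,
    conv_forward,
    dropout_forward,
    lstm_forward,
    lstm_step,
    maxpool_forward,
    pooled_mask,
    relu_forward,
    sigmoid,
)


def conv_oracle(X, W, b):
    """Loop-based cross-correlation for comparison."""
    B, L, C = X.shape
    F, k, _ = W.shape
    out = np.zeros((B, L - k + 1, F))
    for bi in range(B):
        for s in range(L - k + 1):
            for f in range(F):
                out[bi, s, f] = np.sum(X[bi, s : s + k, :] * W[f]) + b[f]
    return out


def maxpool_oracle(Z, m):
    B, S, F = Z.shape
    P = S // m
    out = np.zeros((B, P, F))
    for bi in range(B):
        for p in range(P):
            for f in range(F):
                out[bi, p, f] = Z[bi, p * m : (p + 1) * m, f].max()
    return out


class TestConv:
    def test_zero_input_zero_bias_gives_zero(self):
        Z, _ = conv_forward(np.zeros((2, 10, 4)), np.zeros((3, 5, 4)), np.zeros(3))
        assert np.all(Z == 0)

    def test_motif_detector(self):
        # filter matching "GA" on a one-channel-per-base input flags the motif
        seq = "ACGAGA"
        onehot = np.zeros((1, 6, 4))
        for i, c in enumerate(seq):
            onehot[0, i, "ACGU".index(c)] = 1.0
        W = np.zeros((1, 2, 4))
        W[0, 0, 2] = 1.0  # G at offset 0
        W[0, 1, 0] = 1.0  # A at offset 1
        Z, _ = conv_forward(onehot, W, np.zeros(1))
        # windows AC, CG, GA, AG, GA -> full matches score 2
        np.testing.assert_array_equal(Z[0, :, 0], [0, 0, 2, 0, 2])

    def test_output_width_formula(self):
        Z, _ = conv_forward(np.zeros((1, 100, 4)), np.zeros((2, 5, 4)), np.zeros(2))
        assert Z.shape == (1, 96, 2)

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(ValueError):
            conv_forward(np.zeros((1, 3, 4)), np.zeros((2, 5, 4)), np.zeros(2))

    def test_matches_loop_oracle_on_random_tensors(self, rng):
        for _ in range(100):
            B, L, C = rng.integers(1, 4), rng.integers(5, 15), rng.integers(1, 5)
            F, k = rng.integers(1, 5), rng.integers(1, 6)
            X = rng.standard_normal((B, L, C))
            W = rng.standard_normal((F, k, C))
            b = rng.standard_normal(F)
            Z, _ = conv_forward(X, W, b)
            np.testing.assert_allclose(Z, conv_oracle(X, W, b), atol=1e-12)


class TestReluAndPool:
    def test_relu_basics(self):
        out, _ = relu_forward(np.array([-1.0, 0.0, 2.0]))
        np.testing.assert_array_equal(out, [0.0, 0.0, 2.0])
        again, _ = relu_forward(out)
        np.testing.assert_array_equal(again, out)  # idempotent

    def test_pool_simple_row(self):
        Z = np.array([1.0, 3.0, 2.0, 0.0]).reshape(1, 4, 1)
        V, _ = maxpool_forward(Z, 2)
        np.testing.assert_array_equal(V[0, :, 0], [3.0, 2.0])

    def test_pool_size_one_is_identity(self, rng):
        Z = rng.standard_normal((2, 7, 3))
        V, _ = maxpool_forward(Z, 1)
        np.testing.assert_array_equal(V, Z)

    def test_matches_brute_force_on_random_maps(self, rng):
        for _ in range(100):
            B, S, F = 1, int(rng.integers(2, 12)), int(rng.integers(1, 6))
            m = int(rng.integers(1, S + 1))
            Z = rng.standard_normal((B, S, F))
            V, _ = maxpool_forward(Z, m)
            np.testing.assert_array_equal(V, maxpool_oracle(Z, m))

    def test_pool_remainder_dropped(self, rng):
        Z = rng.standard_normal((4, 9, 4))
        V, _ = maxpool_forward(Z, 2)
        assert V.shape == (4, 4, 4)


class TestLstm:
    @staticmethod
    def zero_params(in_dim, H):
        return LstmParams(
            Wx=np.zeros((in_dim, 4 * H)),
            Wh=np.zeros((H, 4 * H)),
            b=np.zeros(4 * H),
            pci=np.zeros(H),
            pcf=np.zeros(H),
            pco=np.zeros(H),
        )

    def test_zero_weights_closed_form(self):
        # all gates sigma(0)=0.5, candidate tanh(0)=0 -> c=h=0
        p = self.zero_params(3, 2)
        h, c, _ = lstm_step(np.zeros((1, 3)), np.zeros((1, 2)), np.zeros((1, 2)), p)
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_large_forget_bias_retains_memory(self):
        H = 2
        p = self.zero_params(3, H)
        p.b[H : 2 * H] = 10.0  # forget gate saturated open
        c_prev = np.array([[0.7, -0.4]])
        _, c, _ = lstm_step(np.zeros((1, 3)), np.zeros((1, H)), c_prev, p)
        np.testing.assert_allclose(c, c_prev, atol=1e-3)

    def test_hidden_state_bounded(self, rng):
        p = LstmParams(
            Wx=rng.standard_normal((3, 8)) * 5,
            Wh=rng.standard_normal((2, 8)) * 5,
            b=rng.standard_normal(8) * 5,
            pci=rng.standard_normal(2),
            pcf=rng.standard_normal(2),
            pco=rng.standard_normal(2),
        )
        h, _, _ = lstm_step(
            rng.standard_normal((4, 3)) * 10,
            rng.standard_normal((4, 2)),
            rng.standard_normal((4, 2)),
            p,
        )
        assert np.all(np.abs(h) < 1.0)

    def test_step_matches_hand_coded_reference(self, rng):
        """Elementwise reference computation of the gate equations."""
        in_dim, H, B = 5, 3, 2
        p = LstmParams(
            Wx=rng.standard_normal((in_dim, 4 * H)),
            Wh=rng.standard_normal((H, 4 * H)),
            b=rng.standard_normal(4 * H),
            pci=rng.standard_normal(H),
            pcf=rng.standard_normal(H),
            pco=rng.standard_normal(H),
        )
        x = rng.standard_normal((B, in_dim))
        h0 = rng.standard_normal((B, H))
        c0 = rng.standard_normal((B, H))
        h, c, _ = lstm_step(x, h0, c0, p)

        for bi in range(B):
            pre = x[bi] @ p.Wx + h0[bi] @ p.Wh + p.b
            zi, zf, zg, zo = np.split(pre, 4)
            i = 1 / (1 + np.exp(-(zi + p.pci * c0[bi])))
            f = 1 / (1 + np.exp(-(zf + p.pcf * c0[bi])))
            g = np.tanh(zg)
            c_ref = f * c0[bi] + i * g
            o = 1 / (1 + np.exp(-(zo + p.pco * c_ref)))
            h_ref = o * np.tanh(c_ref)
            np.testing.assert_allclose(c[bi], c_ref, atol=1e-6)
            np.testing.assert_allclose(h[bi], h_ref, atol=1e-6)

    def test_trailing_pad_does_not_change_final_state(self, rng):
        in_dim, H, T = 4, 3, 6
        p = LstmParams(
            Wx=rng.standard_normal((in_dim, 4 * H)),
            Wh=rng.standard_normal((H, 4 * H)),
            b=rng.standard_normal(4 * H),
            pci=rng.standard_normal(H) * 0.1,
            pcf=rng.standard_normal(H) * 0.1,
            pco=rng.standard_normal(H) * 0.1,
        )
        X = rng.standard_normal((1, T, in_dim))
        h_full, _, _ = lstm_forward(X, np.ones((1, T)), p)
        Xpad = np.concatenate([X, rng.standard_normal((1, 3, in_dim))], axis=1)
        mask = np.concatenate([np.ones((1, T)), np.zeros((1, 3))], axis=1)
        h_pad, _, _ = lstm_forward(Xpad, mask, p)
        np.testing.assert_allclose(h_pad, h_full, atol=1e-12)

    def test_empty_valid_region_rejected(self):
        p = self.zero_params(2, 2)
        with pytest.raises(ValueError):
            lstm_forward(np.zeros((1, 4, 2)), np.zeros((1, 4)), p)

    def test_palindrome_with_tied_weights_gives_equal_halves(self, rng):
        p = LstmParams(
            Wx=rng.standard_normal((2, 12)),
            Wh=rng.standard_normal((3, 12)),
            b=rng.standard_normal(12),
            pci=rng.standard_normal(3) * 0.1,
            pcf=rng.standard_normal(3) * 0.1,
            pco=rng.standard_normal(3) * 0.1,
        )
        row = rng.standard_normal((1, 1, 2))
        X = np.concatenate([row, row.copy()[:, ::-1], row], axis=1)  # palindrome
        out, _ = bilstm_forward(X, np.ones((1, 3)), p, p)
        np.testing.assert_allclose(out[:, :3], out[:, 3:], atol=1e-12)


class TestBatchNorm:
    def test_standardizes_batch(self):
        bn = BatchNorm(1)
        out, _ = bn.forward(np.array([[1.0], [2.0], [3.0]]), train=True)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        # biased sd of standardized output is 1 up to the epsilon guard
        assert out.std() == pytest.approx(1.0, abs=1e-4)

    def test_constant_batch_maps_to_zero(self):
        bn = BatchNorm(1)
        out, _ = bn.forward(np.full((4, 1), 7.0), train=True)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_eval_mode_is_stateless(self, rng):
        bn = BatchNorm(3)
        for _ in range(5):
            bn.forward(rng.standard_normal((8, 3)), train=True)
        X = rng.standard_normal((4, 3))
        a, _ = bn.forward(X, train=False)
        b, _ = bn.forward(X, train=False)
        np.testing.assert_array_equal(a, b)

    def test_train_mode_requires_two_examples(self):
        with pytest.raises(ValueError):
            BatchNorm(2).forward(np.ones((1, 2)), train=True)

    def test_masked_positions_excluded_from_stats_and_zeroed(self):
        bn = BatchNorm(1)
        X = np.array([[[1.0], [2.0], [99.0]], [[3.0], [4.0], [99.0]]])
        mask = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0]])
        out, _ = bn.forward(X, train=True, mask=mask)
        assert np.all(out[:, 2, :] == 0.0)
        valid = out[:, :2, :].ravel()
        assert valid.mean() == pytest.approx(0.0, abs=1e-12)


class TestDropout:
    def test_eval_mode_is_identity(self, rng):
        X = rng.standard_normal((5, 5))
        out, cache = dropout_forward(X, 0.5, train=False, rng=rng)
        assert cache is None
        np.testing.assert_array_equal(out, X)

    def test_inverted_scaling_preserves_expectation(self):
        rng = np.random.default_rng(0)
        X = np.ones((200, 200))
        out, _ = dropout_forward(X, 0.5, train=True, rng=rng)
        assert out.mean() == pytest.approx(1.0, abs=0.02)


def test_pooled_mask_counts_match_unpadded_geometry():
    # n valid positions -> n-k+1 valid conv positions -> floor((n-k+1)/m) pooled
    k, m = 5, 2
    for n, L in [(60, 100), (99, 100), (10, 30)]:
        mask = np.zeros((1, L))
        mask[0, :n] = 1.0
        conv_valid, pool_valid = pooled_mask(mask, k, m)
        assert conv_valid.sum() == n - k + 1
        assert pool_valid.sum() == (n - k + 1) // m


def test_sigmoid_stable_for_extreme_inputs():
    x = np.array([-1000.0, -10.0, 0.0, 10.0, 1000.0])
    out = sigmoid(x)
    assert np.all((out >= 0) & (out <= 1))
    assert out[2] == 0.5
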