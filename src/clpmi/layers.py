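"""NumPy building blocks of the network, each with an explicit backward pass.

Shapes follow the batch-first convention: a length-L input with C
channels is (B, L, C). Every forward function returns its output plus a
cache; the matching backward consumes the cache and the upstream
gradient and returns input and parameter gradients. float64 throughout
so finite-difference gradient checks are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

BN_EPS = 1e-5
BN_MOMENTUM = 0.99

try:  # compiled LSTM scan; the NumPy fallback below is math-identical
    from . import _fast

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is present in the target env
    _fast = None
    _HAVE_NUMBA = False


def sigmoid(x: np.ndarray) -> np.ndarray:
    # exp(-|x|) never overflows, so both branches are safe to evaluate
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


# ---------------------------------------------------------------------------
# convolution (stride 1, valid)

def conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """1-D cross-correlation along the length axis.

    X: (B, L, C); W: (F, k, C); b: (F,). Output (B, L-k+1, F) where each
    entry is the dot product of one sliding window with one filter plus
    its bias.
    """
    B, L, C = X.shape
    F, k, Cw = W.shape
    if Cw != C:
        raise ValueError(f"filter depth {Cw} != input channels {C}")
    if k > L:
        raise ValueError(f"kernel length {k} exceeds input length {L}")
    # windows: (B, L-k+1, C, k)
    Xw = sliding_window_view(X, k, axis=1)
    Z = np.einsum("bsck,fkc->bsf", Xw, W, optimize=True) + b
    return Z, (X, W)


def conv_backward(dZ: np.ndarray, cache):
    X, W = cache
    F, k, C = W.shape
    Xw = sliding_window_view(X, k, axis=1)  # (B, S, C, k)
    dW = np.einsum("bsf,bsck->fkc", dZ, Xw, optimize=True)
    db = dZ.sum(axis=(0, 1))
    dX = np.zeros_like(X)
    S = dZ.shape[1]
    for r in range(k):
        dX[:, r : r + S, :] += dZ @ W[:, r, :]
    return dX, dW, db


def relu_forward(Z: np.ndarray):
    out = np.maximum(Z, 0.0)
    return out, (Z > 0)


def relu_backward(dout: np.ndarray, cache) -> np.ndarray:
    return dout * cache


# ---------------------------------------------------------------------------
# non-overlapping max pooling along the length axis

def maxpool_forward(Z: np.ndarray, m: int):
    """Non-overlapping window maxima; trailing remainder dropped.

    Z: (B, S, F) -> (B, floor(S/m), F).
    """
    B, S, F = Z.shape
    if m < 1:
        raise ValueError("pool size must be >= 1")
    if m > S:
        raise ValueError(f"pool size {m} exceeds input length {S}")
    P = S // m
    Zt = Z[:, : P * m, :].reshape(B, P, m, F)
    if m == 2:  # common case: a single comparison beats generic argmax
        arg = (Zt[:, :, 1, :] > Zt[:, :, 0, :]).astype(np.intp)
        V = np.where(arg, Zt[:, :, 1, :], Zt[:, :, 0, :])
    else:
        V = Zt.max(axis=2)
        arg = Zt.argmax(axis=2)  # (B, P, F)
    return V, (Z.shape, m, arg)


def maxpool_backward(dV: np.ndarray, cache) -> np.ndarray:
    shape, m, arg = cache
    B, S, F = shape
    P = dV.shape[1]
    dZ = np.zeros(shape)
    dZt = dZ[:, : P * m, :].reshape(B, P, m, F)
    bi, pi, fi = np.ogrid[:B, :P, :F]
    dZt[bi, pi, arg, fi] = dV
    return dZ


def pooled_mask(mask: np.ndarray, k: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Propagate a validity mask through conv (kernel k) and pooling (m).

    A conv position is valid when its whole k-window is real input; a
    pooled position when its whole m-window of conv positions is valid.
    This makes outputs on a padded input identical to the unpadded run.
    """
    conv_valid = sliding_window_view(mask, k, axis=1).min(axis=-1)
    S = conv_valid.shape[1]
    P = S // m
    pool_valid = conv_valid[:, : P * m].reshape(mask.shape[0], P, m).min(axis=-1)
    return conv_valid, pool_valid


# ---------------------------------------------------------------------------
# batch normalization (optionally mask-weighted over positions)

@dataclass
class BatchNorm:
    """Per-channel standardization with running statistics.

    In train mode, activations are standardized by the batch mean and
    (biased) variance of valid positions; running statistics are
    tracked with an exponential moving average and used in eval mode.
    Output at masked positions is zeroed so padding never leaks.
    """

    n_channels: int
    eps: float = BN_EPS
    momentum: float = BN_MOMENTUM
    gamma: np.ndarray = field(init=False)
    beta: np.ndarray = field(init=False)
    running_mean: np.ndarray = field(init=False)
    running_var: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gamma = np.ones(self.n_channels)
        self.beta = np.zeros(self.n_channels)
        self.running_mean = np.zeros(self.n_channels)
        self.running_var = np.ones(self.n_channels)

    def forward(self, X: np.ndarray, train: bool, mask: np.ndarray | None = None):
        """X: (..., C); mask broadcasts over the leading axes."""
        flat = X.reshape(-1, self.n_channels)
        w = np.ones(flat.shape[0]) if mask is None else mask.reshape(-1)
        n = w.sum()
        if train:
            if flat.shape[0] < 2:
                raise ValueError("batch normalization needs batch size >= 2")
            mean = (w[:, None] * flat).sum(axis=0) / n
            var = (w[:, None] * (flat - mean) ** 2).sum(axis=0) / n
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean) * inv_std
        out = (w[:, None] * (self.gamma * xhat + self.beta)).reshape(X.shape)
        cache = (xhat, inv_std, w, n, X.shape) if train else None
        return out, cache

    def backward(self, dout: np.ndarray, cache):
        """Returns (dX, dgamma, dbeta) for a train-mode forward."""
        xhat, inv_std, w, n, shape = cache
        dflat = dout.reshape(-1, self.n_channels) * w[:, None]
        dgamma = (dflat * xhat).sum(axis=0)
        dbeta = dflat.sum(axis=0)
        g = dflat * self.gamma
        dX = inv_std * (
            g
            - w[:, None] * g.sum(axis=0) / n
            - w[:, None] * xhat * (g * xhat).sum(axis=0) / n
        )
        return dX.reshape(shape), dgamma, dbeta


# ---------------------------------------------------------------------------
# dropout (inverted scaling, train only)

def dropout_forward(X: np.ndarray, p: float, train: bool, rng: np.random.Generator):
    if not train or p == 0.0:
        return X, None
    keep = (rng.random(X.shape) >= p).astype(X.dtype) / (1.0 - p)
    return X * keep, keep


def dropout_backward(dout: np.ndarray, cache) -> np.ndarray:
    return dout if cache is None else dout * cache


# ---------------------------------------------------------------------------
# dense

def dense_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    return X @ W + b, X


def dense_backward(dout: np.ndarray, cache, W: np.ndarray):
    X = cache
    return dout @ W.T, X.T @ dout, dout.sum(axis=0)


# ---------------------------------------------------------------------------
# peephole LSTM

@dataclass
class LstmParams:
    """Gate parameters; columns of Wx/Wh ordered (input, forget, cell, output).

    Peephole weights (pci, pcf, pco) read the memory cell elementwise,
    the standard diagonal form.
    """

    Wx: np.ndarray  # (in_dim, 4H)
    Wh: np.ndarray  # (H, 4H)
    b: np.ndarray  # (4H,)
    pci: np.ndarray  # (H,)
    pcf: np.ndarray
    pco: np.ndarray

    @property
    def hidden(self) -> int:
        return self.Wh.shape[0]


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    p: LstmParams,
):
    """One peephole-LSTM cell update.

    i = sigma(Wxi x + Whi h + pci*c_prev + bi)
    f = sigma(Wxf x + Whf h + pcf*c_prev + bf)
    c = f*c_prev + i*tanh(Wxc x + Whc h + bc)
    o = sigma(Wxo x + Who h + pco*c + bo)
    h = o*tanh(c)
    """
    return _lstm_step_pre(x_t, x_t @ p.Wx + p.b, h_prev, c_prev, p)


def _lstm_step_pre(
    x_t: np.ndarray,
    pre_x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    p: LstmParams,
):
    """Cell update given the precomputed input projection x_t @ Wx + b."""
    H = p.hidden
    pre = pre_x + h_prev @ p.Wh
    zi, zf, zg, zo = pre[:, :H], pre[:, H : 2 * H], pre[:, 2 * H : 3 * H], pre[:, 3 * H :]
    i = sigmoid(zi + p.pci * c_prev)
    f = sigmoid(zf + p.pcf * c_prev)
    g = np.tanh(zg)
    c = f * c_prev + i * g
    o = sigmoid(zo + p.pco * c)
    tanh_c = np.tanh(c)
    h = o * tanh_c
    cache = (x_t, h_prev, c_prev, i, f, g, o, c, tanh_c)
    return h, c, cache


def _lstm_scan_numpy(Xp: np.ndarray, mask_tb: np.ndarray, p: LstmParams):
    """Pure-NumPy forward scan; same contract as `_fast.lstm_scan`."""
    T, B, H4 = Xp.shape
    H = H4 // 4
    stacked = tuple(np.empty((T, B, H)) for _ in range(8))
    I, F, G, O, C, Tc, Hp, Cp = stacked
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        pre = Xp[t] + h @ p.Wh
        Hp[t], Cp[t] = h, c
        i = sigmoid(pre[:, :H] + p.pci * c)
        f = sigmoid(pre[:, H : 2 * H] + p.pcf * c)
        g = np.tanh(pre[:, 2 * H : 3 * H])
        cn = f * c + i * g
        o = sigmoid(pre[:, 3 * H :] + p.pco * cn)
        tc = np.tanh(cn)
        I[t], F[t], G[t], O[t], C[t], Tc[t] = i, f, g, o, cn, tc
        m = mask_tb[t][:, None]
        h = m * (o * tc) + (1.0 - m) * h
        c = m * cn + (1.0 - m) * c
    return h, c, stacked


def _lstm_scan_back_numpy(dh_final, mask_tb, WhT, p: LstmParams, stacked):
    """Pure-NumPy backward scan; same contract as `_fast.lstm_scan_back`."""
    I, F, G, O, C, Tc, Hp, Cp = stacked
    T, B, H = I.shape
    dpre = np.empty((T, B, 4 * H))
    gpci, gpcf, gpco = np.zeros(H), np.zeros(H), np.zeros(H)
    dh = dh_final.copy()
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        m = mask_tb[t][:, None]
        dh_new = dh * m
        dh_carry = dh * (1.0 - m)
        dc_new = dc * m
        dc_carry = dc * (1.0 - m)

        do = dh_new * Tc[t]
        dzo = do * O[t] * (1.0 - O[t])
        dcn = dc_new + dh_new * O[t] * (1.0 - Tc[t] ** 2) + dzo * p.pco
        gpco += (dzo * C[t]).sum(axis=0)

        di = dcn * G[t]
        df = dcn * Cp[t]
        dg = dcn * I[t]
        dc_prev = dcn * F[t]

        dzi = di * I[t] * (1.0 - I[t])
        dzf = df * F[t] * (1.0 - F[t])
        dzg = dg * (1.0 - G[t] ** 2)
        dc_prev = dc_prev + dzi * p.pci + dzf * p.pcf
        gpci += (dzi * Cp[t]).sum(axis=0)
        gpcf += (dzf * Cp[t]).sum(axis=0)

        dpre[t, :, :H] = dzi
        dpre[t, :, H : 2 * H] = dzf
        dpre[t, :, 2 * H : 3 * H] = dzg
        dpre[t, :, 3 * H :] = dzo
        dh = dpre[t] @ WhT + dh_carry
        dc = dc_prev + dc_carry
    return dpre, gpci, gpcf, gpco


def lstm_forward(X: np.ndarray, mask: np.ndarray, p: LstmParams):
    """Run an LSTM over (B, T, D) inputs, skipping masked steps.

    At masked positions the state is carried through unchanged, so the
    final state equals the state after the last valid step.
    Returns (h_final, c_final, cache).
    """
    if mask.sum() == 0:
        raise ValueError("empty valid region")
    # time-major input projections, hoisted out of the scan; matmul on the
    # transposed view writes a contiguous (T, B, 4H) result directly
    Xp = X.transpose(1, 0, 2) @ p.Wx + p.b
    mask_tb = np.ascontiguousarray(mask.T, dtype=np.float64)
    if _HAVE_NUMBA:
        h, c, *stacked = _fast.lstm_scan(Xp, mask_tb, p.Wh, p.pci, p.pcf, p.pco)
        stacked = tuple(stacked)
    else:
        h, c, stacked = _lstm_scan_numpy(Xp, mask_tb, p)
    return h, c, (X, mask_tb, stacked)


def lstm_backward(dh_final: np.ndarray, cache, p: LstmParams, X_shape):
    """Backpropagate through time from a gradient on the final hidden state."""
    X, mask_tb, stacked = cache
    B, T, D = X_shape
    H = p.hidden
    WhT = np.ascontiguousarray(p.Wh.T)
    if _HAVE_NUMBA:
        dpre, gpci, gpcf, gpco = _fast.lstm_scan_back(
            dh_final, mask_tb, WhT, p.pci, p.pcf, p.pco, *stacked
        )
    else:
        dpre, gpci, gpcf, gpco = _lstm_scan_back_numpy(
            dh_final, mask_tb, WhT, p, stacked
        )
    Hp = stacked[6]
    grads = {
        "Wx": np.tensordot(X, dpre, axes=([0, 1], [1, 0])),
        "Wh": Hp.reshape(T * B, H).T @ dpre.reshape(T * B, 4 * H),
        "b": dpre.sum(axis=(0, 1)),
        "pci": gpci,
        "pcf": gpcf,
        "pco": gpco,
    }
    dX = dpre.transpose(1, 0, 2) @ p.Wx.T  # contiguous batch-major output
    return dX, grads


def bilstm_forward(X: np.ndarray, mask: np.ndarray, pf: LstmParams, pb: LstmParams):
    """Bidirectional scan: forward and time-reversed passes, final states
    concatenated to a (B, 2H) representation."""
    h_f, _, caches_f = lstm_forward(X, mask, pf)
    Xr = X[:, ::-1, :]
    mr = mask[:, ::-1]
    h_b, _, caches_b = lstm_forward(Xr, mr, pb)
    return np.concatenate([h_f, h_b], axis=1), (caches_f, caches_b, X.shape)


def bilstm_backward(dout: np.ndarray, cache, pf: LstmParams, pb: LstmParams):
    caches_f, caches_b, X_shape = cache
    H = pf.hidden
    dX_f, grads_f = lstm_backward(dout[:, :H], caches_f, pf, X_shape)
    dX_b_rev, grads_b = lstm_backward(dout[:, H:], caches_b, pb, X_shape)
    dX = dX_f + dX_b_rev[:, ::-1, :]
    return dX, grads_f, grads_b
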