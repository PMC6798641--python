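"""Numba-accelerated LSTM time-scan kernels.

The recurrent scan is the only part of the network whose cost is
dominated by Python-loop overhead rather than BLAS, so only it gets a
compiled kernel. The math is identical to the NumPy fallback in
:mod:`clpmi.layers`; a unit test asserts the two paths agree.
Importing this module raises ImportError when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Cephes-style scalar exp restricted to non-positive arguments (all the
# sigmoid/tanh forms below use exp(-|x|)): libm exp is the hot spot
# inside the compiled scan, and this rational approximation with exact
# range reduction matches np.exp to ~3e-16 relative accuracy while being
# substantially faster. Coefficients from Cephes exp.c (Moshier). The
# 2^n scaling uses a lookup table since n is confined to [-64, 0].
_LOG2E = 1.4426950408889634073599
_C1 = 6.93145751953125e-1
_C2 = 1.42860682030941723212e-6
_P0 = 1.26177193074810590878e-4
_P1 = 3.02994407707441961300e-2
_P2 = 9.99999999999999999910e-1
_Q0 = 3.00198505138664455042e-6
_Q1 = 2.52448340349684104192e-3
_Q2 = 2.27265548208155028766e-1
_Q3 = 2.00000000000000000005e0
_POW2 = 2.0 ** np.arange(-64, 1).astype(np.float64)


@njit(inline="always")
def _exp_neg(x: float) -> float:
    """exp(x) for x <= 0; returns 0.0 below the useful range."""
    if x < -40.0:
        return 0.0
    n = int(math.floor(_LOG2E * x + 0.5))
    x = x - n * _C1 - n * _C2
    xx = x * x
    px = x * ((_P0 * xx + _P1) * xx + _P2)
    qx = ((_Q0 * xx + _Q1) * xx + _Q2) * xx + _Q3
    return (1.0 + 2.0 * px / (qx - px)) * _POW2[n + 64]


@njit(inline="always")
def _sig(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + _exp_neg(-x))
    e = _exp_neg(x)
    return e / (1.0 + e)


@njit(inline="always")
def _tanh(x: float) -> float:
    # tanh(x) = sign(x) * (1 - e) / (1 + e) with e = exp(-2|x|)
    e = _exp_neg(-2.0 * abs(x))
    t = (1.0 - e) / (1.0 + e)
    return t if x >= 0.0 else -t


@njit(cache=True)
def nussinov_fill(pair_ok, min_loop):
    """Fill the Nussinov DP table: M[i, j] = max nested pairs in seq[i..j].

    pair_ok: (n, n) uint8 pairability matrix. Returns an (n+1, n+1)
    int32 table (the extra row/column keeps the recurrence branch-free),
    identical to the NumPy fallback fill in :mod:`clpmi.structure`.
    """
    n = pair_ok.shape[0]
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pair_ok[i, k]:
                    v = 1 + M[i + 1, k - 1] + M[k + 1, j]
                    if v > best:
                        best = v
            M[i, j] = best
    return M


@njit(cache=True, fastmath=True)
def lstm_scan(Xp, mask_tb, Wh, pci, pcf, pco):
    """Forward scan of a peephole LSTM with mask-gated state carry.

    Xp: (T, B, 4H) precomputed input projections x_t @ Wx + b.
    mask_tb: (T, B) validity mask.
    Returns final (h, c) plus the stacked per-step intermediates the
    backward pass needs: gates i/f/g/o, cell c, tanh(c), and the
    previous h and c at each step.
    """
    T, B, H4 = Xp.shape
    H = H4 // 4
    I = np.empty((T, B, H))
    F = np.empty((T, B, H))
    G = np.empty((T, B, H))
    O = np.empty((T, B, H))
    C = np.empty((T, B, H))
    Tc = np.empty((T, B, H))
    Hp = np.empty((T, B, H))
    Cp = np.empty((T, B, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        pre = Xp[t] + np.dot(h, Wh)
        for b in range(B):
            m = mask_tb[t, b]
            if m == 0.0:
                # state carries through unchanged and the gradients at a
                # masked step are zero, so the gate values are never used;
                # store finite placeholders instead of computing them
                for j in range(H):
                    Hp[t, b, j] = h[b, j]
                    Cp[t, b, j] = c[b, j]
                    I[t, b, j] = 0.0
                    F[t, b, j] = 0.0
                    G[t, b, j] = 0.0
                    O[t, b, j] = 0.0
                    C[t, b, j] = 0.0
                    Tc[t, b, j] = 0.0
                continue
            for j in range(H):
                Hp[t, b, j] = h[b, j]
                Cp[t, b, j] = c[b, j]
                i_ = _sig(pre[b, j] + pci[j] * c[b, j])
                f_ = _sig(pre[b, H + j] + pcf[j] * c[b, j])
                g_ = _tanh(pre[b, 2 * H + j])
                cn = f_ * c[b, j] + i_ * g_
                o_ = _sig(pre[b, 3 * H + j] + pco[j] * cn)
                tc = _tanh(cn)
                I[t, b, j] = i_
                F[t, b, j] = f_
                G[t, b, j] = g_
                O[t, b, j] = o_
                C[t, b, j] = cn
                Tc[t, b, j] = tc
                h[b, j] = m * (o_ * tc) + (1.0 - m) * h[b, j]
                c[b, j] = m * cn + (1.0 - m) * c[b, j]
    return h, c, I, F, G, O, C, Tc, Hp, Cp


@njit(cache=True, fastmath=True)
def lstm_scan_back(dh_final, mask_tb, WhT, pci, pcf, pco, I, F, G, O, C, Tc, Hp, Cp):
    """Backward scan from a gradient on the final hidden state.

    Returns the gate pre-activation gradients (T, B, 4H) plus the three
    peephole-weight gradients; the caller turns dpre into Wx/Wh/b/X
    gradients with batched GEMMs.
    """
    T, B, H = I.shape
    dpre = np.zeros((T, B, 4 * H))
    gpci = np.zeros(H)
    gpcf = np.zeros(H)
    gpco = np.zeros(H)
    dh = dh_final.copy()
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        for b in range(B):
            m = mask_tb[t, b]
            if m == 0.0:
                continue  # dpre stays zero; dh/dc carry through unchanged
            for j in range(H):
                dh_new = dh[b, j] * m
                dh_carry = dh[b, j] * (1.0 - m)
                dc_new = dc[b, j] * m
                dc_carry = dc[b, j] * (1.0 - m)

                do = dh_new * Tc[t, b, j]
                dzo = do * O[t, b, j] * (1.0 - O[t, b, j])
                dcn = (
                    dc_new
                    + dh_new * O[t, b, j] * (1.0 - Tc[t, b, j] ** 2)
                    + dzo * pco[j]
                )
                gpco[j] += dzo * C[t, b, j]

                di = dcn * G[t, b, j]
                df = dcn * Cp[t, b, j]
                dg = dcn * I[t, b, j]
                dc_prev = dcn * F[t, b, j]

                dzi = di * I[t, b, j] * (1.0 - I[t, b, j])
                dzf = df * F[t, b, j] * (1.0 - F[t, b, j])
                dzg = dg * (1.0 - G[t, b, j] ** 2)
                dc_prev += dzi * pci[j] + dzf * pcf[j]
                gpci[j] += dzi * Cp[t, b, j]
                gpcf[j] += dzf * Cp[t, b, j]

                dpre[t, b, j] = dzi
                dpre[t, b, H + j] = dzf
                dpre[t, b, 2 * H + j] = dzg
                dpre[t, b, 3 * H + j] = dzo

                dc[b, j] = dc_prev + dc_carry
                dh[b, j] = dh_carry
        dh += np.dot(dpre[t], WhT)
    return dpre, gpci, gpcf, gpco
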