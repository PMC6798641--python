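"""The cascaded CNN -> BLSTM -> dense classifier.

Two convolutional branches read the one-hot sequence (4 channels) and
structure (3 channels) matrices; each applies conv -> ReLU -> max-pool
-> batch norm -> dropout. The pooled branch outputs are concatenated
channel-wise position by position and scanned by a bidirectional
peephole LSTM whose two final states feed a dense ReLU layer and a
sigmoid output unit. Dropout and batch normalization act after the
pooling, recurrent and dense-ReLU stages; an L2 penalty is applied to
the dense weight matrices only.

Everything is plain NumPy with hand-written gradients; `loss_and_grads`
returns analytic gradients for every trainable parameter so the whole
model can be trained with the Adam update in :class:`Adam`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import (
    BatchNorm,
    LstmParams,
    bilstm_backward,
    bilstm_forward,
    conv_backward,
    conv_forward,
    dense_backward,
    dense_forward,
    dropout_backward,
    dropout_forward,
    maxpool_backward,
    maxpool_forward,
    pooled_mask,
    relu_backward,
    relu_forward,
    sigmoid,
)
from .losses import LossConfig, loss_grad_wrt_p, loss_value

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The recurrent and dense widths (20 and 256) and the dropout rate
    (0.5) are the reference settings; convolution sizes are kept small
    enough for CPU training and are fully configurable.
    """

    n_filters: int = 16
    kernel_len: int = 5
    pool_size: int = 2
    lstm_hidden: int = 20
    fc_hidden: int = 256
    dropout_p: float = 0.5
    l2_lambda: float = 1e-4
    peepholes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_filters", "kernel_len", "pool_size", "lstm_hidden", "fc_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:rows, :cols] if rows >= cols else q.T[:rows, :cols]


def _init_lstm(rng: np.random.Generator, in_dim: int, hidden: int, peepholes: bool) -> LstmParams:
    Wx = _glorot(rng, (in_dim, 4 * hidden), in_dim, hidden)
    Wh = np.concatenate(
        [_orthogonal(rng, hidden, hidden) for _ in range(4)], axis=1
    )
    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
    scale = 1.0 if peepholes else 0.0
    return LstmParams(
        Wx=Wx,
        Wh=Wh,
        b=b,
        pci=scale * rng.uniform(-0.1, 0.1, hidden),
        pcf=scale * rng.uniform(-0.1, 0.1, hidden),
        pco=scale * rng.uniform(-0.1, 0.1, hidden),
    )


class CLPMINetwork:
    """Trainable network instance with explicit parameter dictionary."""

    SEQ_CHANNELS = 4
    STR_CHANNELS = 3

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        F, k = config.n_filters, config.kernel_len
        H, D = config.lstm_hidden, config.fc_hidden
        self.params: dict[str, np.ndarray] = {}
        p = self.params
        p["conv_seq.W"] = _glorot(rng, (F, k, 4), k * 4, F)
        p["conv_seq.b"] = np.zeros(F)
        p["conv_str.W"] = _glorot(rng, (F, k, 3), k * 3, F)
        p["conv_str.b"] = np.zeros(F)
        self.lstm_f = _init_lstm(rng, 2 * F, H, config.peepholes)
        self.lstm_b = _init_lstm(rng, 2 * F, H, config.peepholes)
        for name, lp in (("lstm_f", self.lstm_f), ("lstm_b", self.lstm_b)):
            for attr in ("Wx", "Wh", "b", "pci", "pcf", "pco"):
                p[f"{name}.{attr}"] = getattr(lp, attr)
        p["fc1.W"] = _glorot(rng, (2 * H, D), 2 * H, D)
        p["fc1.b"] = np.zeros(D)
        p["fc2.W"] = _glorot(rng, (D, 1), D, 1)
        p["fc2.b"] = np.zeros(1)
        self.bn_seq = BatchNorm(F)
        self.bn_str = BatchNorm(F)
        self.bn_lstm = BatchNorm(2 * H)
        self.bn_fc = BatchNorm(D)
        self._bn = {
            "bn_seq": self.bn_seq,
            "bn_str": self.bn_str,
            "bn_lstm": self.bn_lstm,
            "bn_fc": self.bn_fc,
        }
        for name, bn in self._bn.items():
            p[f"{name}.gamma"] = bn.gamma
            p[f"{name}.beta"] = bn.beta
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xD0]).generate_state(1)[0]
        )

    # -- sync helpers: params dict is the single source of truth ---------
    def _sync(self) -> None:
        for name in ("lstm_f", "lstm_b"):
            lp = getattr(self, name)
            for attr in ("Wx", "Wh", "b", "pci", "pcf", "pco"):
                setattr(lp, attr, self.params[f"{name}.{attr}"])
        for name, bn in self._bn.items():
            bn.gamma = self.params[f"{name}.gamma"]
            bn.beta = self.params[f"{name}.beta"]

    def _branch_forward(self, X, conv_mask, pool_mask, bn, prefix, train):
        cfg = self.config
        Z, conv_cache = conv_forward(
            X, self.params[f"{prefix}.W"], self.params[f"{prefix}.b"]
        )
        A, relu_cache = relu_forward(Z)
        V, pool_cache = maxpool_forward(A, cfg.pool_size)
        N, bn_cache = bn.forward(V, train, mask=pool_mask)
        D, drop_cache = dropout_forward(N, cfg.dropout_p, train, self._dropout_rng)
        return D, (conv_cache, relu_cache, pool_cache, bn_cache, drop_cache)

    def _branch_backward(self, dout, caches, bn, grads, prefix):
        conv_cache, relu_cache, pool_cache, bn_cache, drop_cache = caches
        d = dropout_backward(dout, drop_cache)
        d, dgamma, dbeta = bn.backward(d, bn_cache)
        grads[f"{bn_name(bn, self._bn)}.gamma"] = dgamma
        grads[f"{bn_name(bn, self._bn)}.beta"] = dbeta
        d = maxpool_backward(d, pool_cache)
        d = relu_backward(d, relu_cache)
        dX, dW, db = conv_backward(d, conv_cache)
        grads[f"{prefix}.W"] = dW
        grads[f"{prefix}.b"] = db
        return dX

    def forward(
        self,
        Xseq: np.ndarray,
        Xstr: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
    ):
        """Compute per-example probabilities; returns (p, cache)."""
        self._sync()
        cfg = self.config
        if Xseq.shape[:2] != Xstr.shape[:2]:
            raise ValueError("sequence and structure branches disagree on shape")
        conv_mask, pool_mask = pooled_mask(mask, cfg.kernel_len, cfg.pool_size)
        if pool_mask.sum(axis=1).min() < 1:
            raise ValueError(
                "an example is too short to survive convolution and pooling"
            )
        out_seq, cache_seq = self._branch_forward(
            Xseq, conv_mask, pool_mask, self.bn_seq, "conv_seq", train
        )
        out_str, cache_str = self._branch_forward(
            Xstr, conv_mask, pool_mask, self.bn_str, "conv_str", train
        )
        merged = np.concatenate([out_seq, out_str], axis=2)  # (B, P, 2F)
        rep, lstm_cache = bilstm_forward(merged, pool_mask, self.lstm_f, self.lstm_b)
        bn_l, bn_l_cache = self.bn_lstm.forward(rep, train)
        drop_l, drop_l_cache = dropout_forward(
            bn_l, cfg.dropout_p, train, self._dropout_rng
        )
        z1, fc1_cache = dense_forward(drop_l, self.params["fc1.W"], self.params["fc1.b"])
        a1, relu1_cache = relu_forward(z1)
        bn_f, bn_f_cache = self.bn_fc.forward(a1, train)
        drop_f, drop_f_cache = dropout_forward(
            bn_f, cfg.dropout_p, train, self._dropout_rng
        )
        z2, fc2_cache = dense_forward(drop_f, self.params["fc2.W"], self.params["fc2.b"])
        prob = sigmoid(z2[:, 0])
        cache = {
            "branch_seq": cache_seq,
            "branch_str": cache_str,
            "lstm": lstm_cache,
            "bn_lstm": bn_l_cache,
            "drop_lstm": drop_l_cache,
            "fc1": fc1_cache,
            "relu1": relu1_cache,
            "bn_fc": bn_f_cache,
            "drop_fc": drop_f_cache,
            "fc2": fc2_cache,
            "prob": prob,
            "n_filters": cfg.n_filters,
        }
        return prob, cache

    def backward(self, dprob: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of the loss for every parameter, given dL/dprob."""
        grads: dict[str, np.ndarray] = {}
        prob = cache["prob"]
        dz2 = (dprob * prob * (1.0 - prob))[:, None]
        d, grads["fc2.W"], grads["fc2.b"] = dense_backward(
            dz2, cache["fc2"], self.params["fc2.W"]
        )
        d = dropout_backward(d, cache["drop_fc"])
        d, grads["bn_fc.gamma"], grads["bn_fc.beta"] = self.bn_fc.backward(
            d, cache["bn_fc"]
        )
        d = relu_backward(d, cache["relu1"])
        d, grads["fc1.W"], grads["fc1.b"] = dense_backward(
            d, cache["fc1"], self.params["fc1.W"]
        )
        d = dropout_backward(d, cache["drop_lstm"])
        d, grads["bn_lstm.gamma"], grads["bn_lstm.beta"] = self.bn_lstm.backward(
            d, cache["bn_lstm"]
        )
        dmerged, grads_f, grads_b = bilstm_backward(
            d, cache["lstm"], self.lstm_f, self.lstm_b
        )
        for attr, g in grads_f.items():
            grads[f"lstm_f.{attr}"] = g
        for attr, g in grads_b.items():
            grads[f"lstm_b.{attr}"] = g
        F = cache["n_filters"]
        self._branch_backward(
            dmerged[:, :, :F], cache["branch_seq"], self.bn_seq, grads, "conv_seq"
        )
        self._branch_backward(
            dmerged[:, :, F:], cache["branch_str"], self.bn_str, grads, "conv_str"
        )
        return grads

    def loss_and_grads(
        self,
        Xseq: np.ndarray,
        Xstr: np.ndarray,
        mask: np.ndarray,
        y: np.ndarray,
        loss_cfg: LossConfig,
        train: bool = True,
    ):
        """Total loss (data term + L2 on dense weights) and its gradients."""
        prob, cache = self.forward(Xseq, Xstr, mask, train=train)
        lam = self.config.l2_lambda
        loss = loss_value(prob, y, loss_cfg) + lam * (
            np.sum(self.params["fc1.W"] ** 2) + np.sum(self.params["fc2.W"] ** 2)
        )
        dprob = loss_grad_wrt_p(prob, y, loss_cfg)
        grads = self.backward(dprob, cache)
        grads["fc1.W"] = grads["fc1.W"] + 2.0 * lam * self.params["fc1.W"]
        grads["fc2.W"] = grads["fc2.W"] + 2.0 * lam * self.params["fc2.W"]
        return loss, grads, prob

    def predict_proba(
        self, Xseq: np.ndarray, Xstr: np.ndarray, mask: np.ndarray, batch_size: int = 256
    ) -> np.ndarray:
        """Eval-mode probabilities (dropout off, running batch-norm stats)."""
        out = []
        for start in range(0, Xseq.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            prob, _ = self.forward(Xseq[sl], Xstr[sl], mask[sl], train=False)
            out.append(prob)
        return np.concatenate(out)

    # -- persistence ------------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        arrays = dict(self.params)
        for name, bn in self._bn.items():
            arrays[f"{name}.running_mean"] = bn.running_mean
            arrays[f"{name}.running_var"] = bn.running_var
        np.savez(
            path,
            __config__=json.dumps({"version": CHECKPOINT_VERSION, **asdict(self.config)}),
            __extra__=json.dumps(extra or {}),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "CLPMINetwork":
        with np.load(path, allow_pickle=False) as bundle:
            meta = json.loads(str(bundle["__config__"]))
            extra = (
                json.loads(str(bundle["__extra__"])) if "__extra__" in bundle else {}
            )
            version = meta.pop("version")
            if version != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {version}")
            net = cls(ModelConfig(**meta))
            for key in net.params:
                net.params[key] = bundle[key]
            for name, bn in net._bn.items():
                bn.running_mean = bundle[f"{name}.running_mean"]
                bn.running_var = bundle[f"{name}.running_var"]
        net.extra_ = extra
        net._sync()
        return net


def bn_name(bn: BatchNorm, registry: dict[str, BatchNorm]) -> str:
    for name, obj in registry.items():
        if obj is bn:
            return name
    raise KeyError("unregistered batch-norm layer")


class Adam:
    """Adam optimizer over a named parameter dictionary."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
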