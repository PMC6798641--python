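"""scikit-learn style estimator wrapping the CNN-BLSTM network.

`HairpinClassifier` follows the fit/predict/predict_proba contract and
composes with scikit-learn model selection. Inputs are biological
rather than tabular: X may be a :class:`~clpmi.io.Dataset`, a sequence
of :class:`~clpmi.io.SequenceRecord`, or a sequence of
``(rna_sequence, dot_bracket_structure)`` string pairs. When X carries
labels (Dataset/records), ``y`` may be omitted.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .encoding import DEFAULT_MAX_LEN, stack_examples, encode_dataset
from .io import Dataset, SequenceRecord
from .losses import LossConfig
from .metrics import evaluate
from .network import Adam, CLPMINetwork, ModelConfig

DECISION_THRESHOLD = 0.5


def _coerce_records(X) -> list[SequenceRecord]:
    if isinstance(X, Dataset):
        return list(X.records)
    records = []
    for i, item in enumerate(X):
        if isinstance(item, SequenceRecord):
            records.append(item)
        else:
            seq, structure = item
            records.append(SequenceRecord(id=f"x{i:06d}", seq=seq, structure=structure))
    return records


class HairpinClassifier(BaseEstimator, ClassifierMixin):
    """Cascaded CNN-BLSTM pre-miRNA hairpin classifier.

    Parameters mirror the reference training protocol: Adam with
    learning rate 0.001 and mini-batches of 128, 300 epochs, focal loss
    with gamma=2 and alpha=0.25 under ~7.4:1 class imbalance, dropout
    0.5 with batch normalization and an L2 penalty on the dense weights.

    Parameters
    ----------
    n_filters, kernel_len, pool_size : int
        Convolution branch geometry (per branch, stride 1).
    lstm_hidden : int
        Recurrent state size per direction (default 20).
    fc_hidden : int
        Dense layer width (default 256).
    dropout_p : float
        Drop probability on pooled, recurrent and dense outputs.
    l2_lambda : float
        Coefficient of the squared-weight penalty on dense matrices.
    loss : {"focal", "weighted_ce", "ce"}
        Training criterion; ``gamma``/``alpha`` apply to focal loss and
        ``class_weights`` to the weighted cross-entropy.
    epochs, batch_size, learning_rate : training protocol.
    pad_len : int or None
        Shared encoding length; None fits it to the training data
        (capped at ``max_len``).
    random_state : int
        Seeds initialization, batching and dropout.

    Attributes
    ----------
    network_ : CLPMINetwork
        The trained network.
    classes_ : ndarray of shape (2,)
        Always ``[0, 1]``.
    pad_len_ : int
        Encoding length fitted on the training set.
    history_ : list of dict
        Per-epoch training loss (and validation metrics when an
        ``eval_set`` was supplied to :meth:`fit`).
    """

    def __init__(
        self,
        n_filters: int = 16,
        kernel_len: int = 5,
        pool_size: int = 2,
        lstm_hidden: int = 20,
        fc_hidden: int = 256,
        dropout_p: float = 0.5,
        l2_lambda: float = 1e-4,
        peepholes: bool = True,
        loss: str = "focal",
        gamma: float = 2.0,
        alpha: float = 0.25,
        class_weights: tuple[float, float] = (0.9, 0.1),
        epochs: int = 300,
        batch_size: int = 128,
        learning_rate: float = 0.001,
        pad_len: Optional[int] = None,
        max_len: int = DEFAULT_MAX_LEN,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_len = kernel_len
        self.pool_size = pool_size
        self.lstm_hidden = lstm_hidden
        self.fc_hidden = fc_hidden
        self.dropout_p = dropout_p
        self.l2_lambda = l2_lambda
        self.peepholes = peepholes
        self.loss = loss
        self.gamma = gamma
        self.alpha = alpha
        self.class_weights = class_weights
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.pad_len = pad_len
        self.max_len = max_len
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_filters=self.n_filters,
            kernel_len=self.kernel_len,
            pool_size=self.pool_size,
            lstm_hidden=self.lstm_hidden,
            fc_hidden=self.fc_hidden,
            dropout_p=self.dropout_p,
            l2_lambda=self.l2_lambda,
            peepholes=self.peepholes,
            seed=self.random_state,
        )

    def _loss_config(self) -> LossConfig:
        return LossConfig(
            kind=self.loss,
            gamma=self.gamma,
            alpha=self.alpha,
            class_weights=tuple(self.class_weights),
        )

    def _encode(self, X, truncate: bool = False):
        records = _coerce_records(X)
        ds = Dataset(records)
        examples = encode_dataset(ds, L=self.pad_len_, truncate=truncate)
        return stack_examples(examples)

    # ------------------------------------------------------------------
    def fit(self, X, y=None, eval_set=None):
        """Train the network.

        Parameters
        ----------
        X : Dataset, sequence of SequenceRecord, or (seq, structure) pairs
        y : array-like of 0/1, optional when X carries labels
        eval_set : optional (X_val, y_val) pair; when given, the full
            metric report on it is appended to ``history_`` each epoch.
        """
        records = _coerce_records(X)
        if y is None:
            y = [rec.label for rec in records]
            if any(label is None for label in y):
                raise ValueError("X carries unlabeled records and y was not given")
        y = np.asarray(y, dtype=np.int64)
        if len(y) != len(records):
            raise ValueError("X and y differ in length")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

        self.pad_len_ = self.pad_len or min(
            max(len(r.seq) for r in records), self.max_len
        )
        self.classes_ = np.array([0, 1])
        Xseq, Xstr, mask, _ = self._encode(records, truncate=True)
        loss_cfg = self._loss_config()
        self.network_ = CLPMINetwork(self._model_config())
        optimizer = Adam(self.network_.params, lr=self.learning_rate)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 0x5E]).generate_state(1)[0]
        )

        n = len(records)
        val = None
        if eval_set is not None:
            X_val, y_val = eval_set
            val_records = _coerce_records(X_val)
            Vseq, Vstr, vmask, vlab = self._encode(val_records, truncate=True)
            y_val = np.asarray(
                y_val if y_val is not None else vlab, dtype=np.int64
            )
            val = (Vseq, Vstr, vmask, y_val)

        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if idx.size < 2:
                    continue  # batch norm needs at least two examples
                loss, grads, _ = self.network_.loss_and_grads(
                    Xseq[idx], Xstr[idx], mask[idx], y[idx], loss_cfg, train=True
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (loss={loss}) at epoch {epoch}"
                    )
                optimizer.step(self.network_.params, grads)
                epoch_loss += loss
                n_batches += 1
            row = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
            if val is not None:
                scores = self.network_.predict_proba(val[0], val[1], val[2])
                row.update(evaluate(scores, val[3]).as_dict())
            self.history_.append(row)
        return self

    # ------------------------------------------------------------------
    def decision_scores(self, X) -> np.ndarray:
        """Predicted probability of the positive (hairpin) class."""
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")
        Xseq, Xstr, mask, _ = self._encode(X, truncate=True)
        return self.network_.predict_proba(Xseq, Xstr, mask)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= DECISION_THRESHOLD).astype(np.int64)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Persist weights, architecture and fitted metadata to ``path``."""
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")
        self.network_.save(
            path, extra={**self.get_params(), "pad_len_": int(self.pad_len_)}
        )

    @classmethod
    def load(cls, path) -> "HairpinClassifier":
        net = CLPMINetwork.load(path)
        extra = dict(net.extra_)
        pad_len = extra.pop("pad_len_")
        extra["class_weights"] = tuple(extra["class_weights"])
        clf = cls(**extra)
        clf.network_ = net
        clf.pad_len_ = pad_len
        clf.classes_ = np.array([0, 1])
        clf.history_ = []
        return clf
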