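"""Training orchestration: stratified splitting, five-fold
cross-validation, and held-out test evaluation.

The default protocol holds out a stratified 10% test set and runs
five-fold cross-validation on the remaining 90% (an 80/20 split is also
supported via ``test_fraction=0.2``). Fold reports are aggregated by
unweighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .estimator import HairpinClassifier
from .io import Dataset
from .losses import LossConfig
from .metrics import MetricsReport, evaluate
from .network import ModelConfig


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.001
    epochs: int = 300
    n_folds: int = 5
    test_fraction: float = 0.10
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_idx: np.ndarray  # indices into the original dataset
    val_idx: np.ndarray


def split_dataset(
    ds: Dataset, cfg: TrainConfig
) -> tuple[np.ndarray, list[FoldSplit]]:
    """Stratified test holdout plus stratified K folds of the remainder.

    Returns (test_indices, folds); folds partition the non-test data.
    """
    labels = np.array([rec.label for rec in ds])
    if any(label is None for label in ds.labels):
        raise ValueError("all records must be labeled before splitting")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"each class needs at least n_folds={cfg.n_folds} members, "
            f"got counts {tuple(counts)}"
        )
    idx = np.arange(len(ds))
    cv_idx, test_idx = train_test_split(
        idx,
        test_size=cfg.test_fraction,
        stratify=labels,
        random_state=cfg.seed,
        shuffle=True,
    )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    folds = [
        FoldSplit(fold_id=i, train_idx=cv_idx[tr], val_idx=cv_idx[va])
        for i, (tr, va) in enumerate(skf.split(cv_idx, labels[cv_idx]))
    ]
    return test_idx, folds


def make_classifier(
    model_cfg: ModelConfig, train_cfg: TrainConfig
) -> HairpinClassifier:
    return HairpinClassifier(
        n_filters=model_cfg.n_filters,
        kernel_len=model_cfg.kernel_len,
        pool_size=model_cfg.pool_size,
        lstm_hidden=model_cfg.lstm_hidden,
        fc_hidden=model_cfg.fc_hidden,
        dropout_p=model_cfg.dropout_p,
        l2_lambda=model_cfg.l2_lambda,
        peepholes=model_cfg.peepholes,
        loss=train_cfg.loss.kind,
        gamma=train_cfg.loss.gamma,
        alpha=train_cfg.loss.alpha,
        class_weights=train_cfg.loss.class_weights,
        epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size,
        learning_rate=train_cfg.learning_rate,
        random_state=model_cfg.seed,
    )


def train_fold(
    ds: Dataset,
    fold: FoldSplit,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[HairpinClassifier, pd.DataFrame]:
    """Train on one fold, tracing loss and the seven validation metrics
    per epoch. Returns (fitted classifier, trace)."""
    train_ds = ds.subset(fold.train_idx)
    val_ds = ds.subset(fold.val_idx)
    clf = make_classifier(model_cfg, train_cfg)
    clf.fit(train_ds, eval_set=(val_ds, None))
    trace = pd.DataFrame(clf.history_)
    return clf, trace


def cross_validate(
    ds: Dataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    folds: list[FoldSplit] | None = None,
) -> tuple[list[MetricsReport], dict]:
    """Five-fold (by default) cross-validation.

    Returns per-fold reports and their unweighted-mean summary.
    """
    if folds is None:
        _, folds = split_dataset(ds, train_cfg)
    reports = []
    for fold in folds:
        clf = make_classifier(model_cfg, train_cfg)
        clf.fit(ds.subset(fold.train_idx))
        scores = clf.decision_scores(ds.subset(fold.val_idx))
        labels = [ds.records[i].label for i in fold.val_idx]
        reports.append(evaluate(scores, labels))
    mean = {
        key: float(np.mean([r.as_dict()[key] for r in reports]))
        for key in reports[0].as_dict()
    }
    return reports, mean


def evaluate_test(clf: HairpinClassifier, test_ds: Dataset) -> MetricsReport:
    """Eval-mode metrics of a fitted classifier on a held-out set."""
    if len(test_ds) == 0:
        raise ValueError("empty test set")
    labels = [rec.label for rec in test_ds]
    if any(label is None for label in labels):
        raise ValueError("test records must be labeled")
    return evaluate(clf.decision_scores(test_ds), labels)
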