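"""Cross-validated training and evaluation of masked-network variants.

The loss is the mean of the per-head binary cross-entropies plus the
cross-entropy of the combined (weighted-average) prediction, minimized
with Adam.  Performance is AUC-ROC, computed with the Mann-Whitney
rank-sum formula (average ranks, so ties count one half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .network import SparseNet

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    n_folds: int = 10
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int | None = None  # None = full batch
    class_weighting: bool = True
    patience: int = 10  # early stopping on validation loss; 0 disables
    val_fraction: float = 0.0  # >0 carves a stratified validation split
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0.0 <= self.val_fraction < 0.5):
            raise ValueError("val_fraction must lie in [0, 0.5)")


@dataclass
class FoldResult:
    fold_id: int
    auc: float
    test_scores: np.ndarray
    test_index: np.ndarray
    state: dict  # trained parameter snapshot


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC-ROC = P(score_pos > score_neg) + 0.5 * P(tie) (Mann-Whitney).

    Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks implement the half-tie rule
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def stratified_kfold(
    labels: Sequence[int], k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split; class proportions per fold within one sample
    of the global proportions; reproducible per seed."""
    labels = np.asarray(labels).ravel().astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train.copy(), test.copy())
        for train, test in skf.split(np.zeros(len(labels)), labels)
    ]


class Adam:
    """Standard Adam over a dict of parameter arrays, updated in place."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def class_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequency."""
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2).astype(float)
    w = len(y) / (2.0 * np.maximum(counts, 1.0))
    return w[y]


def train_model(
    model: SparseNet,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Fit the network in place; returns the loss history.

    With ``cfg.val_fraction > 0`` and ``cfg.patience > 0`` a stratified
    validation split drives early stopping (best-state restore).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).ravel().astype(int)
    rng = np.random.default_rng(cfg.seed)
    x_val = y_val = None
    if cfg.val_fraction > 0 and cfg.patience > 0:
        n_val_splits = max(2, int(round(1.0 / cfg.val_fraction)))
        if np.bincount(y, minlength=2).min() >= n_val_splits:
            tr, va = stratified_kfold(y, n_val_splits, seed=cfg.seed)[0]
            x_val, y_val = x[va], y[va]
            x, y = x[tr], y[tr]
    sw = class_weights(y) if cfg.class_weighting else None
    opt = Adam(model.param_dict(), lr=cfg.learning_rate)
    history: list[float] = []
    best_val = np.inf
    best_state = None
    wait = 0
    n = len(y)
    for epoch in range(cfg.epochs):
        if cfg.batch_size is None or cfg.batch_size >= n:
            loss, grads = model.loss_and_grads(x, y, sample_weight=sw, rng=rng)
            opt.step(grads)
            history.append(loss)
        else:
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, grads = model.loss_and_grads(
                    x[idx], y[idx],
                    sample_weight=None if sw is None else sw[idx],
                    rng=rng,
                )
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / max(n_batches, 1))
        if x_val is not None:
            val_loss, _ = model.loss_and_grads(
                x_val, y_val, training=False
            )
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = model.get_state()
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    logger.info("early stopping at epoch %d", epoch + 1)
                    break
    if best_state is not None:
        model.set_state(best_state)
    return history


def cross_validate(
    build_model,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> list[FoldResult]:
    """Stratified k-fold CV.  ``build_model(fold_seed)`` must return a fresh
    ``SparseNet``; each fold trains independently and is scored by AUC on
    its held-out samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).ravel().astype(int)
    results: list[FoldResult] = []
    for fold_id, (tr, te) in enumerate(stratified_kfold(y, cfg.n_folds, cfg.seed)):
        model = build_model(cfg.seed + 1000 * fold_id)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * fold_id})
        train_model(model, x[tr], y[tr], fold_cfg)
        scores = model.predict(x[te]).combined_probability
        results.append(
            FoldResult(
                fold_id=fold_id,
                auc=auc_roc(scores, y[te]),
                test_scores=scores,
                test_index=te,
                state=model.get_state(),
            )
        )
    return results
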