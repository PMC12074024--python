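"""Functional training interface and leakage-free cross-validation.

Thin wrappers over :class:`~moeclock.estimator.MoEAgeRegressor` plus the
grouped 10-fold cross-validation protocol: inside each fold, gene filters
and normalization statistics are fitted on the training samples only, so no
statistic of a held-out fold ever reaches the model that is scored on it.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .estimator import MoEAgeRegressor, augment_gaussian, lr_at  # noqa: F401 (re-export)
from .evaluation import compute_mae_r2
from .io import AgingGenePool, ExpressionMatrix, SampleAnnotation, align_annotations
from .losses import LossConfig
from .preprocessing import CountNormalizer


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings (defaults follow the published recipe)."""

    lr0: float = 5e-3
    decay: float = 0.8
    decay_every: int = 20
    batch_size: int = 512
    epochs: int = 200
    aug_copies: int = 30
    aug_sd: float = 0.5
    seed: int = 0
    n_experts: int = 2
    hidden_widths: tuple[int, ...] = (640, 256, 128, 64)
    dropout_rate: float = 0.3
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.aug_copies < 0:
            raise ValueError("aug_copies must be non-negative")


def _estimator_from(cfg: TrainConfig) -> MoEAgeRegressor:
    return MoEAgeRegressor(
        n_experts=cfg.n_experts, hidden_widths=tuple(cfg.hidden_widths),
        dropout_rate=cfg.dropout_rate, margin=cfg.loss.margin, lam=cfg.loss.lam,
        gamma=cfg.loss.gamma, pool_fraction=cfg.loss.pool_fraction, top_k=cfg.loss.top_k,
        lr=cfg.lr0, lr_decay=cfg.decay, decay_every=cfg.decay_every,
        batch_size=cfg.batch_size, epochs=cfg.epochs, aug_copies=cfg.aug_copies,
        aug_sd=cfg.aug_sd, random_state=cfg.seed,
    )


def train(expr: ExpressionMatrix, annotations: Sequence[SampleAnnotation],
          pool: AgingGenePool | None, cfg: TrainConfig,
          validation: tuple | None = None) -> tuple[MoEAgeRegressor, dict]:
    """Train on a normalized expression matrix; returns (estimator, history)."""
    ann = align_annotations(expr, annotations)
    est = _estimator_from(cfg)
    pool_idx = pool.indices_in(expr.gene_ids) if pool is not None else None
    est.fit(expr.values, ann["age"].to_numpy(float),
            status=ann["status"].to_numpy(object), pool_indices=pool_idx,
            validation_data=validation)
    return est, est.history_


def stratified_folds(annotations: Sequence[SampleAnnotation], n_folds: int, seed: int) -> np.ndarray:
    """Fold index per sample, stratified by status and age quartile."""
    ages = np.array([a.age for a in annotations])
    status = np.array([a.status for a in annotations], dtype=object)
    quartile = np.searchsorted(np.quantile(ages, [0.25, 0.5, 0.75]), ages)
    strata = np.array([f"{s}:{q}" for s, q in zip(status, quartile)], dtype=object)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(annotations), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(annotations)), strata)):
        assignment[test_idx] = f
    return assignment


@dataclasses.dataclass
class CVReport:
    fold_assignment: np.ndarray
    per_fold: pd.DataFrame
    pooled: dict
    normalizers: list


def crossvalidate(counts: ExpressionMatrix, annotations: Sequence[SampleAnnotation],
                  pool: AgingGenePool | None, cfg: TrainConfig, n_folds: int = 10,
                  normalizer: CountNormalizer | None = None) -> CVReport:
    """Grouped k-fold cross-validation without test-set leakage.

    Normalization (gene filters, centers, scales) is refit on every
    training split; pooled MAE/R² are computed over the concatenated
    held-out predictions of healthy samples.
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    ann = align_annotations(counts, annotations)
    by_id = {a.sample_id: a for a in annotations}
    assignment = stratified_folds([by_id[s] for s in counts.sample_ids], n_folds, cfg.seed)
    ages = ann["age"].to_numpy(float)
    status = ann["status"].to_numpy(object)

    rows, normalizers = [], []
    pooled_pred, pooled_true = [], []
    for f in range(n_folds):
        test_mask = assignment == f
        if not test_mask.any() or test_mask.all():
            raise ValueError(f"fold {f} is degenerate")
        if not np.any(status[test_mask] == "healthy"):
            raise ValueError(f"fold {f} contains no healthy samples; healthy MAE undefined")
        train_expr = ExpressionMatrix(
            counts.values[~test_mask], counts.gene_ids,
            [s for s, t in zip(counts.sample_ids, test_mask) if not t])
        test_expr = ExpressionMatrix(
            counts.values[test_mask], counts.gene_ids,
            [s for s, t in zip(counts.sample_ids, test_mask) if t])
        norm = (CountNormalizer() if normalizer is None
                else CountNormalizer(**normalizer.get_params()))
        norm.fit(train_expr)
        normalizers.append(norm)
        Xtr, Xte = norm.transform(train_expr), norm.transform(test_expr)

        est = _estimator_from(cfg)
        pool_idx = pool.indices_in(Xtr.gene_ids) if pool is not None else None
        est.fit(Xtr.values, ages[~test_mask], status=status[~test_mask], pool_indices=pool_idx)
        pred = est.predict(Xte.values)

        healthy_te = status[test_mask] == "healthy"
        m, r2 = compute_mae_r2(pred[healthy_te], ages[test_mask][healthy_te])
        rows.append({"fold": f, "n_test": int(test_mask.sum()),
                     "n_healthy_test": int(healthy_te.sum()), "mae_healthy": m,
                     "r2_healthy": r2})
        pooled_pred.append(pred[healthy_te])
        pooled_true.append(ages[test_mask][healthy_te])

    pooled_pred = np.concatenate(pooled_pred)
    pooled_true = np.concatenate(pooled_true)
    m, r2 = compute_mae_r2(pooled_pred, pooled_true)
    return CVReport(
        fold_assignment=assignment,
        per_fold=pd.DataFrame(rows),
        pooled={"mae_healthy": m, "r2_healthy": r2, "n": int(pooled_true.size)},
        normalizers=normalizers,
    )
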