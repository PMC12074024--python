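"""Training objective: MAE, Hinge-MAE, the saliency-alignment (AHK) loss,
and their status-routed combination.

Healthy subjects are scored with plain mean absolute error against
chronological age.  Unhealthy subjects use the Hinge-MAE: absolute errors
below a margin Δ cost nothing, because their biological age may
legitimately deviate from the chronological label by up to Δ years.  The
AHK ("alignment to human knowledge") term rewards concentrating saliency
mass on a curated aging-gene pool; it lives in [-1, 0] with -1 meaning all
top-ranked saliency mass is on pool genes.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from . import engine as E
from . import network as net
from .engine import Tensor
from .io import AgingGenePool

_STATUS = ("healthy", "unhealthy")


@dataclasses.dataclass
class LossConfig:
    """Weights and margins of the total objective.

    margin (Δ, years), lam (λ, prediction-loss weight), gamma (γ, AHK
    weight), pool_fraction (share of the pool sampled each epoch for the
    AHK term), top_k (length of the importance-ranked gene list).
    """

    margin: float = 5.0
    lam: float = 30.0
    gamma: float = 100.0
    pool_fraction: float = 0.10
    top_k: int = 1000

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not (0.0 < self.pool_fraction <= 1.0):
            raise ValueError("pool_fraction must be in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")


@dataclasses.dataclass
class LossBreakdown:
    total: float
    prediction_term: float
    ahk_term: float
    per_expert_D: list[float]


def mae(pred, target) -> float:
    """Mean absolute error in years."""
    pred, target = np.asarray(pred, dtype=float).ravel(), np.asarray(target, dtype=float).ravel()
    if pred.size == 0:
        raise ValueError("mae of empty input is undefined")
    if pred.shape != target.shape:
        raise ValueError("pred and target must have equal length")
    return float(np.mean(np.abs(pred - target)))


def hinge_mae(pred, target, margin: float) -> float:
    """MAE with a dead-zone: errors strictly below the margin cost nothing."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    pred, target = np.asarray(pred, dtype=float).ravel(), np.asarray(target, dtype=float).ravel()
    if pred.size == 0:
        raise ValueError("hinge_mae of empty input is undefined")
    if pred.shape != target.shape:
        raise ValueError("pred and target must have equal length")
    err = np.abs(pred - target)
    return float(np.mean(np.where(err >= margin, err, 0.0)))


def _top_k_order(importance: np.ndarray, top_k: int) -> np.ndarray:
    """Indices of the top_k genes by importance, descending, stable ties."""
    k = min(top_k, importance.size)
    return np.argsort(-importance, kind="stable")[:k]


def ahk_loss(saliency, pool_subset, top_k: int) -> float:
    """Alignment-to-human-knowledge loss on a per-gene saliency vector.

    Ranks genes by |saliency|, keeps the top_k, and returns minus the
    fraction of that top-k saliency mass carried by pool genes — a value in
    [-1, 0].
    """
    s = np.abs(np.asarray(saliency, dtype=float).ravel())
    pool_subset = np.asarray(sorted(set(int(i) for i in pool_subset)), dtype=int)
    if pool_subset.size == 0:
        raise ValueError("pool subset must be non-empty")
    if top_k < 1 or top_k > s.size:
        raise ValueError("top_k must be in [1, d]")
    order = _top_k_order(s, top_k)
    denom = s[order].sum()
    if denom <= 0:
        warnings.warn("all-zero saliency: AHK loss undefined, returning 0", RuntimeWarning)
        return 0.0
    in_pool = order[np.isin(order, pool_subset)]
    return float(-s[in_pool].sum() / denom)


def sample_pool_subset(pool, fraction: float, seed: int) -> np.ndarray:
    """Uniform without-replacement sample of round(fraction × N) pool members.

    ``pool`` may be an :class:`AgingGenePool` (returns gene IDs) or a
    sequence of gene/column indices (returns indices).  Always at least one
    element; reproducible from the seed.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(pool, AgingGenePool):
        items = np.asarray(sorted(pool.genes), dtype=object)
    else:
        items = np.asarray(sorted(set(np.asarray(pool).tolist())))
    if items.size == 0:
        raise ValueError("pool is empty")
    n = max(1, int(np.rint(fraction * items.size)))
    rng = np.random.default_rng(seed)
    return rng.choice(items, size=n, replace=False)


def _routed_error(y_out: Tensor, yc: np.ndarray, healthy_mask: np.ndarray, margin: float) -> Tensor:
    """Per-sample error column: MAE route for healthy, hinge for unhealthy."""
    err = E.tabs(y_out - Tensor(yc[:, None]))
    hinge_gate = (err.data >= margin).astype(float)   # piecewise-constant factor
    route = healthy_mask[:, None] + (1.0 - healthy_mask[:, None]) * hinge_gate
    return err * Tensor(route)


def total_loss_graph(model: net.MoEModel, X: np.ndarray, yc, status, cfg: LossConfig,
                     pool_subset=None, mode: str = "train", rng=None,
                     update_stats: bool = False) -> tuple[LossBreakdown, Tensor]:
    """Build the differentiable total objective; returns (breakdown, node).

    total = λ · mean_s Σ_i p_si · routed_err_si  +  γ · L_AHK, with the AHK
    term computed from the gate-weighted per-expert input gradients of the
    current batch (gates weight but are not differentiated with respect to
    the input; parameter gradients flow through them).
    """
    X = np.asarray(X, dtype=np.float64)
    yc = np.asarray(yc, dtype=np.float64).ravel()
    status = np.asarray(status, dtype=object).ravel()
    if not (X.shape[0] == yc.size == status.size):
        raise ValueError("X, yc and status must agree on the number of samples")
    bad = set(status) - set(_STATUS)
    if bad:
        raise ValueError(f"unknown status label(s): {sorted(bad)}")
    healthy_mask = (status == "healthy").astype(float)

    use_ahk = cfg.gamma > 0 and pool_subset is not None
    Xt = Tensor(X, requires_grad=use_ahk)
    p = net.gate_out(model, Xt, mode, rng, update_stats)
    per_expert_D: list[float] = []
    routed_cols = []
    saliencies = []
    for i in range(model.config.n_experts):
        y_i = net.expert_out(model, i, Xt, mode, rng, update_stats)
        routed = _routed_error(y_i, yc, healthy_mask, cfg.margin)
        routed_cols.append(routed)
        per_expert_D.append(float(routed.data.mean()))
        if use_ahk:
            (s_i,) = E.grad(E.tsum(y_i), [Xt], create_graph=True)
            saliencies.append(s_i)

    # prediction term: mean over samples of the gate-weighted routed error
    pred_term = E.tmean(
        E.tsum(
            sum(p[:, i:i + 1] * routed_cols[i] for i in range(model.config.n_experts)),
            axis=1,
        )
    )

    if use_ahk:
        s_total = sum(p[:, i:i + 1] * saliencies[i] for i in range(model.config.n_experts))
        imp = E.tmean(E.tabs(s_total), axis=0)              # aggregated per-gene importance
        imp_np = imp.data
        pool_idx = np.asarray(sorted(set(int(i) for i in pool_subset)), dtype=int)
        if pool_idx.size == 0:
            raise ValueError("pool subset must be non-empty")
        order = _top_k_order(imp_np, min(cfg.top_k, imp_np.size))
        denom_np = imp_np[order].sum()
        if denom_np <= 0:
            warnings.warn("all-zero saliency: AHK term set to 0", RuntimeWarning)
            ahk = Tensor(0.0)
        else:
            in_pool = order[np.isin(order, pool_idx)]
            num = E.tsum(imp[in_pool]) if in_pool.size else Tensor(0.0)
            ahk = E.neg(num * E.power(E.tsum(imp[order]), -1.0))
    else:
        ahk = Tensor(0.0)

    total = cfg.lam * pred_term + cfg.gamma * ahk
    breakdown = LossBreakdown(
        total=float(total.data),
        prediction_term=float(pred_term.data),
        ahk_term=float(ahk.data),
        per_expert_D=per_expert_D,
    )
    return breakdown, total


def total_loss(model: net.MoEModel, X, yc, status, cfg: LossConfig,
               pool_subset=None, mode: str = "train", rng=None) -> LossBreakdown:
    """Evaluate the total objective without keeping the graph."""
    breakdown, _ = total_loss_graph(model, X, yc, status, cfg, pool_subset, mode, rng)
    return breakdown
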