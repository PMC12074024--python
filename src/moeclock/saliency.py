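"""Gradient saliency: per-expert and gated per-gene importance, gene ranking.

The saliency of an expert at an input x is the partial derivative of its
scalar output with respect to each input gene, computed in eval mode so
attribution is deterministic.  The model-level saliency is the gate-weighted
sum of expert saliencies; by default the gate weights act as constants of
the input-differentiation (the derivative of the gate itself can be included
behind a flag).
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import engine as E
from . import network as net
from .engine import Tensor


@dataclasses.dataclass
class SaliencyMap:
    """Per-gene importance; shape (m, d) per-sample or (d,) aggregated."""

    values: np.ndarray
    scope: str = "per-sample"           # "per-sample" | "aggregated"
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise FloatingPointError("saliency contains non-finite values")


@dataclasses.dataclass
class GeneRanking:
    """Gene IDs with importance scores in non-increasing order."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")


def _as_batch(model: net.MoEModel, x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    if x.shape[1] != model.config.input_dim:
        raise ValueError("input dimension does not match the model")
    return x


def expert_saliency(model: net.MoEModel, i: int, x) -> SaliencyMap:
    """∂F_i(x)/∂x in eval mode; one row per sample (rows are independent)."""
    xb = _as_batch(model, x)
    Xt = Tensor(xb, requires_grad=True)
    y = net.expert_out(model, i, Xt, mode="eval")
    (s,) = E.grad(E.tsum(y), [Xt])
    values = s.data if np.asarray(x).ndim > 1 else s.data[0]
    return SaliencyMap(values=values, scope="per-sample")


def total_saliency(model: net.MoEModel, x, include_gate_grad: bool = False) -> SaliencyMap:
    """Gate-weighted sum of expert saliencies, Σ_i p_i · ∂F_i/∂x.

    With ``include_gate_grad=True`` the full product derivative
    ∂(Σ_i p_i F_i)/∂x is returned instead (gate differentiated too).
    """
    xb = _as_batch(model, x)
    Xt = Tensor(xb, requires_grad=True)
    if include_gate_grad:
        p = net.gate_out(model, Xt, mode="eval")
        ys = [net.expert_out(model, i, Xt, mode="eval") for i in range(model.config.n_experts)]
        mix = sum(p[:, i:i + 1] * ys[i] for i in range(model.config.n_experts))
        (s,) = E.grad(E.tsum(mix), [Xt])
        values = s.data
    else:
        p = net.gate_forward(model, xb, mode="eval")
        values = np.zeros_like(xb)
        for i in range(model.config.n_experts):
            s_i = expert_saliency(model, i, xb).values
            values += p[:, i:i + 1] * s_i
    values = values if np.asarray(x).ndim > 1 else values[0]
    return SaliencyMap(values=values, scope="per-sample")


def aggregate_saliency(maps) -> SaliencyMap:
    """Mean over samples of |per-sample saliency| — the per-gene importance."""
    if isinstance(maps, SaliencyMap):
        stacked = np.atleast_2d(maps.values)
    else:
        rows = [np.atleast_2d(m.values if isinstance(m, SaliencyMap) else m) for m in maps]
        if not rows:
            raise ValueError("need at least one saliency map")
        d = rows[0].shape[1]
        if any(r.shape[1] != d for r in rows):
            raise ValueError("saliency maps disagree on the number of genes")
        stacked = np.concatenate(rows, axis=0)
    return SaliencyMap(values=np.mean(np.abs(stacked), axis=0), scope="aggregated")


def rank_genes(saliency_map: SaliencyMap, gene_ids: Sequence[str], k: int) -> GeneRanking:
    """Top-k genes by importance, descending; ties broken by gene ID."""
    imp = np.asarray(saliency_map.values, dtype=float).ravel()
    gene_ids = [str(g) for g in gene_ids]
    if len(gene_ids) != imp.size:
        raise ValueError("gene_ids length must match the saliency vector")
    if k <= 0 or k > imp.size:
        raise ValueError("k must be in [1, d]")
    order = sorted(range(imp.size), key=lambda j: (-imp[j], gene_ids[j]))[:k]
    return GeneRanking(gene_ids=[gene_ids[j] for j in order], scores=imp[order])
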