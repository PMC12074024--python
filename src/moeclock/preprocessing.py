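"""Leakage-free normalization of expression counts into model-ready matrices.

The recipe is standard bulk RNA-seq practice: counts-per-million on library
size, log(1 + CPM), then per-gene z-scoring — with every statistic (gene
filters, centers, scales) computed on the *training* samples only and
frozen into a :class:`NormalizationModel` that is applied unchanged to any
later data.  For data already on a continuous normalized scale the library
step and the log can both be switched off, leaving plain per-gene
standardization.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix

FORMAT_VERSION = 1
_DEGENERATE_SD = 1e-8


@dataclasses.dataclass
class NormalizationModel:
    """Frozen per-gene transform fitted on training samples only."""

    kept_gene_ids: list[str]
    per_gene_center: np.ndarray
    per_gene_scale: np.ndarray
    library_size_divisor_policy: str = "cpm"  # "cpm" | "none"
    log1p: bool = True

    def __post_init__(self):
        self.per_gene_center = np.asarray(self.per_gene_center, dtype=np.float64)
        self.per_gene_scale = np.asarray(self.per_gene_scale, dtype=np.float64)
        k = len(self.kept_gene_ids)
        if self.per_gene_center.shape != (k,) or self.per_gene_scale.shape != (k,):
            raise ValueError("center/scale lengths must equal the number of kept genes")
        if np.any(self.per_gene_scale <= 0):
            raise ValueError("per-gene scale must be strictly positive")
        if self.library_size_divisor_policy not in ("cpm", "none"):
            raise ValueError(f"unknown library policy {self.library_size_divisor_policy!r}")

    def to_json(self, path=None) -> str:
        doc = {
            "format_version": FORMAT_VERSION,
            "kept_gene_ids": list(self.kept_gene_ids),
            "per_gene_center": self.per_gene_center.tolist(),
            "per_gene_scale": self.per_gene_scale.tolist(),
            "library_size_divisor_policy": self.library_size_divisor_policy,
            "log1p": self.log1p,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NormalizationModel":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "{" not in str(source) else source
        doc = json.loads(text)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported normalization model version")
        return cls(
            kept_gene_ids=doc["kept_gene_ids"],
            per_gene_center=np.asarray(doc["per_gene_center"]),
            per_gene_scale=np.asarray(doc["per_gene_scale"]),
            library_size_divisor_policy=doc["library_size_divisor_policy"],
            log1p=doc["log1p"],
        )


def _pre_transform(values: np.ndarray, policy: str, log1p: bool) -> np.ndarray:
    """Library scaling + log, applied per sample before gene standardization."""
    x = np.asarray(values, dtype=np.float64)
    if policy == "cpm":
        lib = x.sum(axis=1, keepdims=True)
        if np.any(lib <= 0):
            raise ValueError("a sample has non-positive library size; cannot compute CPM")
        x = x / lib * 1e6
    if log1p:
        x = np.log1p(x)
    return x


class CountNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer implementing the fit/apply normalization split.

    Parameters
    ----------
    min_total_count : int
        Keep genes with at least this many total counts across training samples.
    min_samples_expressed : int
        Keep genes expressed (> 0) in at least this many training samples.
    library_size : str
        "cpm" for counts-per-million on per-sample library size, "none" for
        data already on a continuous scale (may be negative).
    log1p : bool
        Apply log(1 + x) after the library step.
    """

    def __init__(self, min_total_count: int = 10, min_samples_expressed: int = 2,
                 library_size: str = "cpm", log1p: bool = True):
        self.min_total_count = min_total_count
        self.min_samples_expressed = min_samples_expressed
        self.library_size = library_size
        self.log1p = log1p

    def fit(self, X: ExpressionMatrix, y=None):
        values = X.values
        if self.library_size == "cpm" and np.any(values < 0):
            raise ValueError("counts must be non-negative under the CPM policy")
        if self.library_size == "cpm":
            expressed = (values > 0).sum(axis=0)
            totals = values.sum(axis=0)
            keep = (totals >= self.min_total_count) & (expressed >= self.min_samples_expressed)
        else:
            keep = np.ones(values.shape[1], dtype=bool)
        if not np.any(keep):
            raise ValueError("all genes were filtered out; relax the filters")
        kept_ids = [g for g, k in zip(X.gene_ids, keep) if k]
        x = _pre_transform(values, self.library_size, self.log1p)[:, keep]
        center = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        degenerate = sd < _DEGENERATE_SD
        scale = np.where(degenerate, 1.0, sd)
        self.model_ = NormalizationModel(
            kept_gene_ids=kept_ids,
            per_gene_center=center,
            per_gene_scale=scale,
            library_size_divisor_policy=self.library_size,
            log1p=self.log1p,
        )
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        return apply_normalization(self.model_, X)


def fit_normalization(counts: ExpressionMatrix, min_total_count: int = 10,
                      min_samples_expressed: int = 2, library_size: str = "cpm",
                      log1p: bool = True) -> NormalizationModel:
    """Fit gene filters, centers and scales on (training) samples only."""
    norm = CountNormalizer(min_total_count, min_samples_expressed, library_size, log1p)
    return norm.fit(counts).model_


def apply_normalization(model: NormalizationModel, counts: ExpressionMatrix) -> ExpressionMatrix:
    """Apply a frozen normalization model; no statistics from the new samples."""
    pos = {g: j for j, g in enumerate(counts.gene_ids)}
    missing = [g for g in model.kept_gene_ids if g not in pos]
    if missing:
        raise ValueError(f"input is missing kept gene(s): {missing[:5]}")
    x = _pre_transform(counts.values, model.library_size_divisor_policy, model.log1p)
    cols = [pos[g] for g in model.kept_gene_ids]
    x = x[:, cols]
    x = (x - model.per_gene_center) / model.per_gene_scale
    return ExpressionMatrix(x, list(model.kept_gene_ids), list(counts.sample_ids))
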