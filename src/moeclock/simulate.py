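"""Synthetic multi-cohort expression data with a known age signal.

The generator emulates the structure of a multi-cohort bulk RNA-seq aging
compilation: a subset of causal genes whose (normalized-scale) expression
tracks *biological* age linearly, per-cohort baseline shifts, disease
groups whose biological age is offset from chronological age by a known
number of years, and Gaussian measurement noise.  Because slopes, offsets
and noise are all known, parameter recovery and predicted-age-difference
behaviour can be checked exactly downstream.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from .io import AgingGenePool, ExpressionMatrix, SampleAnnotation

_TISSUES = ("brain", "retina", "heart", "lung", "blood")


@dataclasses.dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort draw.

    ``effect_size`` is the standard deviation of per-gene slopes
    (normalized-expression units per year); ``noise_sd`` is i.i.d. Gaussian
    measurement noise on the same scale.  Disease groups are
    ``(label, n, age_offset_years)`` triples: members' biological age is
    chronological age plus the offset.
    """

    n_healthy: int = 300
    disease_groups: Sequence[tuple[str, int, float]] = ()
    d_genes: int = 2000
    n_causal: int = 100
    frac_causal_in_pool: float = 0.5
    pool_size: int = 200
    age_range: tuple[float, float] = (20.0, 90.0)
    effect_size: float = 0.1
    noise_sd: float = 1.0
    n_cohorts: int = 3
    quadratic: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.d_genes:
            raise ValueError("n_causal cannot exceed d_genes")
        if not (0.0 <= self.frac_causal_in_pool <= 1.0):
            raise ValueError("frac_causal_in_pool must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if self.pool_size > self.d_genes:
            raise ValueError("pool_size cannot exceed d_genes")


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows: the simulated population itself."""

    causal_gene_ids: frozenset[str]
    per_gene_slope: np.ndarray          # length d; zero for non-causal genes
    biological_age: np.ndarray          # per generated sample, years
    pool: AgingGenePool
    gene_ids: list[str]
    cohort_intercepts: np.ndarray       # (n_cohorts, d)
    noise_sd: float
    age_range: tuple[float, float]
    quadratic: bool = False

    def to_json(self, path=None) -> str:
        doc = {
            "causal_gene_ids": sorted(self.causal_gene_ids),
            "per_gene_slope": self.per_gene_slope.tolist(),
            "biological_age": self.biological_age.tolist(),
            "pool": sorted(self.pool.genes),
            "gene_ids": list(self.gene_ids),
            "cohort_intercepts": self.cohort_intercepts.tolist(),
            "noise_sd": self.noise_sd,
            "age_range": list(self.age_range),
            "quadratic": self.quadratic,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _expression_for(truth: GroundTruth, bio_age: np.ndarray, cohorts: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    age_term = bio_age[:, None] ** 2 if truth.quadratic else bio_age[:, None]
    signal = age_term * truth.per_gene_slope[None, :]
    base = truth.cohort_intercepts[cohorts]
    noise = rng.normal(0.0, truth.noise_sd, size=signal.shape) if truth.noise_sd > 0 else 0.0
    return signal + base + noise


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, list[SampleAnnotation], GroundTruth]:
    """Draw a full synthetic cohort: expression, annotations, ground truth."""
    rng = np.random.default_rng(spec.seed)
    d = spec.d_genes
    gene_ids = [f"G{j:05d}" for j in range(d)]

    causal_idx = rng.choice(d, size=spec.n_causal, replace=False)
    slopes = np.zeros(d)
    slopes[causal_idx] = rng.normal(0.0, spec.effect_size, size=spec.n_causal)

    # Aging gene pool: a fraction of causal genes plus non-causal padding.
    n_causal_in_pool = int(round(spec.frac_causal_in_pool * min(spec.n_causal, spec.pool_size)))
    pool_causal = rng.choice(causal_idx, size=n_causal_in_pool, replace=False)
    non_causal = np.setdiff1d(np.arange(d), causal_idx)
    n_pad = spec.pool_size - n_causal_in_pool
    pool_pad = rng.choice(non_causal, size=n_pad, replace=False) if n_pad > 0 else np.array([], dtype=int)
    pool_idx = np.concatenate([pool_causal, pool_pad])
    pool = AgingGenePool(frozenset(gene_ids[j] for j in pool_idx))

    intercepts = rng.normal(0.0, 1.0, size=(spec.n_cohorts, d))

    groups = [("healthy", spec.n_healthy, 0.0)] + [tuple(g) for g in spec.disease_groups]
    n_total = sum(int(g[1]) for g in groups)
    chron = rng.uniform(spec.age_range[0], spec.age_range[1], size=n_total)
    cohorts = rng.integers(0, spec.n_cohorts, size=n_total)
    sexes = rng.choice(["male", "female"], size=n_total)

    offsets = np.concatenate([np.full(int(n), float(delta)) for _, n, delta in groups])
    labels = sum(([str(lab)] * int(n) for lab, n, _ in groups), [])
    bio = chron + offsets

    truth = GroundTruth(
        causal_gene_ids=frozenset(gene_ids[j] for j in causal_idx),
        per_gene_slope=slopes,
        biological_age=bio,
        pool=pool,
        gene_ids=gene_ids,
        cohort_intercepts=intercepts,
        noise_sd=spec.noise_sd,
        age_range=spec.age_range,
        quadratic=spec.quadratic,
    )
    values = _expression_for(truth, bio, cohorts, rng)

    sample_ids = [f"S{i:05d}" for i in range(n_total)]
    annotations = [
        SampleAnnotation(
            sample_id=sample_ids[i],
            age=float(chron[i]),
            status="healthy" if labels[i] == "healthy" else "unhealthy",
            condition="none" if labels[i] == "healthy" else labels[i],
            tissue=_TISSUES[cohorts[i] % len(_TISSUES)],
            sex=str(sexes[i]),
            cohort=f"c{cohorts[i]}",
        )
        for i in range(n_total)
    ]
    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    return expr, annotations, truth


def generate_group(truth: GroundTruth, label: str, n: int, age_offset: float, seed: int,
                   prefix: str = "R") -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Draw fresh samples from the same simulated population.

    Used for held-out control groups and replicate disease groups that must
    share the causal structure of an existing cohort without reusing its
    samples.
    """
    rng = np.random.default_rng(seed)
    lo, hi = truth.age_range
    chron = rng.uniform(lo, hi, size=n)
    cohorts = rng.integers(0, truth.cohort_intercepts.shape[0], size=n)
    bio = chron + age_offset
    values = _expression_for(truth, bio, cohorts, rng)
    sample_ids = [f"{prefix}{seed}_{i:05d}" for i in range(n)]
    healthy = label == "healthy"
    annotations = [
        SampleAnnotation(
            sample_id=sample_ids[i],
            age=float(chron[i]),
            status="healthy" if healthy else "unhealthy",
            condition="none" if healthy else label,
            tissue=_TISSUES[cohorts[i] % len(_TISSUES)],
            cohort=f"c{cohorts[i]}",
        )
        for i in range(n)
    ]
    return ExpressionMatrix(values, list(truth.gene_ids), sample_ids), annotations


def inject_label_noise(annotations: Sequence[SampleAnnotation], sd: float, seed: int) -> list[SampleAnnotation]:
    """Add Gaussian noise to age labels (clamped at 0); all else untouched."""
    if sd < 0:
        raise ValueError("label noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for a in annotations:
        age = a.age + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        out.append(dataclasses.replace(a, age=max(0.0, age)))
    return out
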