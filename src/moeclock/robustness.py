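"""Perturbation models for robustness curves: Gaussian, dropout, PCA, label.

The PCA-noise model decomposes each sample on the principal components of
the *training* data, keeps the leading components that explain 95% of the
variance, and rescales the coefficients on the remaining "noise" components
by a factor ρ; ρ=1 is the identity and ρ=0 removes the minor-component
tail.  Injectors preserve shapes and never touch annotations.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .evaluation import compute_mae_r2

KINDS = ("gaussian", "dropout", "pca", "label")

#: default sweep magnitudes mirroring the published robustness experiments
DEFAULT_GAUSSIAN_SWEEP = (0.0, 0.5, 1.5, 3.0, 5.0, 10.0)
DEFAULT_PCA_SWEEP = (0.0, 1.0, 2.0, 5.0, 7.0, 10.0, 20.0)


@dataclasses.dataclass
class NoiseSpec:
    """One perturbation: kind, magnitude (sd / rate / ρ / label-sd), seed."""

    kind: str
    magnitude: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.kind == "dropout" and self.magnitude > 1:
            raise ValueError("dropout rate must be in [0, 1]")


@dataclasses.dataclass
class PCABasis:
    """Principal decomposition of training data with the 95%-variance cut L."""

    mean: np.ndarray
    components: np.ndarray              # (n_components, d), row-orthonormal
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    L: int
    variance_threshold: float


def inject_gaussian(X: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Add i.i.d. Gaussian(0, sd) noise to every entry."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    X = np.asarray(X, dtype=np.float64)
    if sd == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X + rng.normal(0.0, sd, size=X.shape)


def inject_dropout(X: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Zero each entry independently with the given probability."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    X = np.asarray(X, dtype=np.float64)
    if rate == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X * (rng.random(X.shape) >= rate)


def fit_pca_basis(X_train: np.ndarray, variance_threshold: float = 0.95) -> PCABasis:
    """Full principal decomposition of training samples (mean-centered).

    L is the smallest number of leading components whose cumulative
    explained-variance fraction reaches the threshold.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("need at least two training samples")
    if np.allclose(X_train, X_train[0], atol=0):
        raise ValueError("training matrix is constant; no variance to decompose")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X_train)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    hit = np.flatnonzero(cum >= variance_threshold - 1e-9)
    L = int(hit[0] + 1) if hit.size else int(ratio.size)
    return PCABasis(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=ratio,
        L=L,
        variance_threshold=variance_threshold,
    )


def inject_pca_noise(X: np.ndarray, basis: PCABasis, rho: float) -> np.ndarray:
    """Rescale each sample's minor-component coefficients by ρ.

    Implemented additively, x̃ = x + (ρ−1)·(tail reconstruction), so ρ=1 is
    exactly the identity even for samples outside the training span.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != basis.components.shape[1]:
        raise ValueError("input dimension does not match the PCA basis")
    tail = basis.components[basis.L:]
    if tail.shape[0] == 0:
        return X.copy()
    coeff_tail = (X - basis.mean) @ tail.T
    return X + (rho - 1.0) * (coeff_tail @ tail)


def robustness_sweep(predictor, X_test: np.ndarray, y_test: np.ndarray, specs,
                     replicates: int = 5, pca_basis: PCABasis | None = None) -> pd.DataFrame:
    """Mean held-out MAE/R² per noise spec over seeded replicates.

    ``predictor`` is any fitted object with ``predict``.  ``kind="label"``
    perturbs the evaluation-time labels (a proxy for label uncertainty; the
    training-label experiment is run by refitting with noisy annotations).
    Rows come back ordered by (kind, magnitude).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    X_test = np.asarray(X_test, dtype=np.float64)
    y_test = np.asarray(y_test, dtype=np.float64).ravel()
    rows = []
    for spec in sorted(specs, key=lambda s: (s.kind, s.magnitude)):
        maes, r2s = [], []
        for r in range(replicates):
            sub_seed = (int(spec.seed) + 7919 * r) % (2 ** 31)
            Xp, yp = X_test, y_test
            if spec.kind == "gaussian":
                Xp = inject_gaussian(X_test, spec.magnitude, sub_seed)
            elif spec.kind == "dropout":
                Xp = inject_dropout(X_test, spec.magnitude, sub_seed)
            elif spec.kind == "pca":
                if pca_basis is None:
                    raise ValueError("pca noise requires a fitted PCABasis")
                Xp = inject_pca_noise(X_test, pca_basis, spec.magnitude)
            elif spec.kind == "label":
                rng = np.random.default_rng(sub_seed)
                yp = y_test + (rng.normal(0.0, spec.magnitude, size=y_test.shape)
                               if spec.magnitude > 0 else 0.0)
            m, r2 = compute_mae_r2(predictor.predict(Xp), yp)
            maes.append(m)
            r2s.append(r2 if r2 is not None else np.nan)
        rows.append({"kind": spec.kind, "magnitude": spec.magnitude,
                     "mae": float(np.mean(maes)), "r2": float(np.nanmean(r2s)),
                     "replicates": replicates})
    return pd.DataFrame(rows)
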