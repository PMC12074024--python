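"""Accuracy metrics, predicted-age differences (PAD) and significance verdicts.

PAD = predicted − chronological age; positive PADs suggest older-than-
chronological biology.  A condition shows *accelerated aging* ("A.") when
its PADs are significantly larger than those of healthy controls unseen
during training; a significant shift in the other direction is reported as
decelerated ("D."), anything else as "N.".
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, r2_score

from .io import SampleAnnotation


@dataclasses.dataclass
class PADRecord:
    sample_id: str
    predicted_age: float
    chronological_age: float
    pad: float
    group: str

    def __post_init__(self):
        expected = self.predicted_age - self.chronological_age
        if abs(self.pad - expected) > 1e-9:
            raise ValueError("pad must equal predicted - chronological")


@dataclasses.dataclass
class SignificanceVerdict:
    condition: str
    p_value: float
    mean_pad_condition: float
    mean_pad_control: float
    verdict: str                       # "A." | "N." | "D."
    neg_log10_p: float


def compute_mae_r2(pred, truth) -> tuple[float, float | None]:
    """(MAE in years, R²); R² is None when the truth is constant."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.size == 0:
        raise ValueError("empty input")
    m = float(mean_absolute_error(truth, pred))
    if pred.size < 2 or np.ptp(truth) == 0:
        return m, None
    return m, float(r2_score(truth, pred))


def compute_pads(predictor, X, annotations: Sequence[SampleAnnotation]) -> list[PADRecord]:
    """One PAD record per sample, grouped by condition (healthy → control)."""
    X = np.asarray(X, dtype=np.float64)
    if len(annotations) != X.shape[0]:
        raise ValueError("annotations must align with the rows of X")
    for a in annotations:
        if a.age is None or not np.isfinite(a.age):
            raise ValueError(f"sample {a.sample_id!r} has no usable age")
    pred = np.asarray(predictor.predict(X), dtype=float).ravel()
    return [
        PADRecord(
            sample_id=a.sample_id,
            predicted_age=float(p),
            chronological_age=float(a.age),
            pad=float(p - a.age),
            group="control" if a.status == "healthy" else a.condition,
        )
        for p, a in zip(pred, annotations)
    ]


def pad_significance(condition_pads, control_pads, alpha: float = 0.05,
                     condition: str = "condition", backend: str = "t",
                     n_permutations: int = 10000, seed: int = 0) -> SignificanceVerdict:
    """Two-sample location test between condition and control PADs.

    Backends: ``"t"`` (Welch's unequal-variance t-test, default) or
    ``"permutation"`` (exact two-sided permutation test on the difference
    of means, seeded).  The accelerated verdict requires both significance
    at level alpha and a positive direction.
    """
    cond = np.asarray(condition_pads, dtype=float).ravel()
    ctrl = np.asarray(control_pads, dtype=float).ravel()
    if cond.size < 3 or ctrl.size < 3:
        raise ValueError("each group needs at least three PADs")
    if backend == "t":
        p = float(stats.ttest_ind(cond, ctrl, equal_var=False).pvalue)
    elif backend == "permutation":
        res = stats.permutation_test(
            (cond, ctrl), lambda a, b, axis=-1: np.mean(a, axis=axis) - np.mean(b, axis=axis),
            permutation_type="independent", alternative="two-sided",
            n_resamples=n_permutations, rng=np.random.default_rng(seed), vectorized=True,
        )
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    mean_c, mean_k = float(cond.mean()), float(ctrl.mean())
    if p < alpha and mean_c > mean_k:
        verdict = "A."
    elif p < alpha and mean_c < mean_k:
        verdict = "D."
    else:
        verdict = "N."
    return SignificanceVerdict(
        condition=condition, p_value=p, mean_pad_condition=mean_c,
        mean_pad_control=mean_k, verdict=verdict,
        neg_log10_p=float(-np.log10(max(p, 1e-300))),
    )


def age_bin(age: float) -> str:
    """young < 30, adult 30–70 (inclusive), old > 70 years."""
    if age < 30:
        return "young"
    if age <= 70:
        return "adult"
    return "old"


def grouped_report(predictor, X, annotations: Sequence[SampleAnnotation],
                   groupings: Sequence[str] = ("sex", "tissue", "age_bin")) -> pd.DataFrame:
    """Per-group (n, MAE, R²) rows for each requested grouping key.

    Keys come from the annotation fields plus the derived ``age_bin``.
    Age bins with no members are reported with n=0 and missing metrics.
    """
    X = np.asarray(X, dtype=np.float64)
    pred = np.asarray(predictor.predict(X), dtype=float).ravel()
    ages = np.array([a.age for a in annotations], dtype=float)
    frames = []
    for key in groupings:
        if key == "age_bin":
            labels = np.array([age_bin(a.age) for a in annotations], dtype=object)
            categories = ["young", "adult", "old"]
        else:
            if not hasattr(annotations[0], key):
                raise ValueError(f"unknown grouping key {key!r}")
            labels = np.array([getattr(a, key) for a in annotations], dtype=object)
            categories = sorted(set(labels))
        rows = []
        for cat in categories:
            mask = labels == cat
            n = int(mask.sum())
            if n == 0:
                rows.append({"grouping": key, "group": cat, "n": 0,
                             "mae": np.nan, "r2": np.nan})
                continue
            m, r2 = compute_mae_r2(pred[mask], ages[mask])
            rows.append({"grouping": key, "group": cat, "n": n, "mae": m,
                         "r2": np.nan if r2 is None else r2})
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)
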