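"""Reading and writing expression tables, sample annotations and gene pools.

All formats are plain delimited text: expression tables carry one header
row of sample IDs and one leading column of gene IDs (genes in rows by
default, transposable on read), annotations are CSV with named columns,
and gene pools are one identifier per line with ``#`` comments.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STATUS = ("healthy", "unhealthy")
VALID_SEX = ("male", "female", "unknown")

ANNOTATION_COLUMNS = ("sample_id", "age", "status", "condition", "tissue", "sex", "cohort")


@dataclasses.dataclass
class ExpressionMatrix:
    """Samples × genes expression values with ordered ID indices."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        m, d = self.values.shape
        if d != len(self.gene_ids) or m != len(self.sample_ids):
            raise ValueError("value matrix shape does not match ID lists")
        if m < 1 or d < 1:
            raise ValueError("expression matrix must have at least one sample and one gene")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} ID: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclasses.dataclass
class SampleAnnotation:
    """Per-sample metadata: chronological age and grouping covariates."""

    sample_id: str
    age: float
    status: str = "healthy"
    condition: str = "none"
    tissue: str = "unknown"
    sex: str = "unknown"
    cohort: str = "unknown"

    def __post_init__(self):
        self.age = float(self.age)
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError(f"sample {self.sample_id!r}: age must be a non-negative number")
        self.status = str(self.status).lower()
        if self.status not in VALID_STATUS:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown status {self.status!r} "
                f"(expected one of {VALID_STATUS})"
            )
        self.sex = str(self.sex).lower()
        if self.sex not in VALID_SEX:
            raise ValueError(f"sample {self.sample_id!r}: unknown sex {self.sex!r}")
        if self.status == "healthy":
            self.condition = "none"


@dataclasses.dataclass
class AgingGenePool:
    """A curated set of gene identifiers known to relate to aging."""

    genes: frozenset[str]

    def __post_init__(self):
        self.genes = frozenset(str(g) for g in self.genes)
        if not self.genes:
            raise ValueError("aging gene pool must be non-empty")

    @property
    def size(self) -> int:
        return len(self.genes)

    def indices_in(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Column indices of pool members within ``gene_ids`` (exact match)."""
        return np.flatnonzero(np.isin(np.asarray(gene_ids, dtype=object), sorted(self.genes)))


def _first_duplicate(ids: Iterable[str]):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path, orientation: str = "genes-in-rows", sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression table into samples × genes orientation.

    ``orientation`` describes the file layout: ``genes-in-rows`` (default,
    first column gene IDs, header sample IDs) or ``samples-in-rows``.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = sep or _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    dup = _first_duplicate(df.index.astype(str))
    if dup is not None:
        raise ValueError(f"duplicate ID in first column: {dup!r}")
    dup = _first_duplicate(df.columns.astype(str))
    if dup is not None:
        raise ValueError(f"duplicate ID in header: {dup!r}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.argwhere(np.isnan(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric or missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "genes-in-rows":
        return ExpressionMatrix(values.T, list(df.index.astype(str)), list(df.columns.astype(str)))
    return ExpressionMatrix(values, list(df.columns.astype(str)), list(df.index.astype(str)))


def write_expression(expr: ExpressionMatrix, path, orientation: str = "genes-in-rows", sep: str | None = None) -> None:
    sep = sep or _sep_for(path)
    df = expr.to_frame()
    if orientation == "genes-in-rows":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=sep)


def read_annotations(path, sep: str | None = None) -> list[SampleAnnotation]:
    """Read sample annotations; missing optional columns default to unknown/none."""
    sep = sep or ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for required in ("sample_id", "age"):
        if required not in df.columns:
            raise ValueError(f"annotation file missing required column {required!r}")
    records = []
    for _, row in df.iterrows():
        kwargs = {"sample_id": str(row["sample_id"]), "age": float(row["age"])}
        for col, default in (
            ("status", "healthy"),
            ("condition", "none"),
            ("tissue", "unknown"),
            ("sex", "unknown"),
            ("cohort", "unknown"),
        ):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = str(row[col])
            else:
                kwargs[col] = default
        records.append(SampleAnnotation(**kwargs))
    return records


def write_annotations(annotations: Sequence[SampleAnnotation], path) -> None:
    df = pd.DataFrame([dataclasses.asdict(a) for a in annotations], columns=ANNOTATION_COLUMNS)
    df.to_csv(path, index=False)


def read_gene_pool(path) -> AgingGenePool:
    """Read a one-gene-per-line pool file; '#' starts a comment."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    if not genes:
        raise ValueError(f"gene pool file {path} contains no gene IDs")
    return AgingGenePool(frozenset(genes))


def write_gene_pool(pool: AgingGenePool, path) -> None:
    Path(path).write_text("\n".join(sorted(pool.genes)) + "\n")


def align_annotations(expr: ExpressionMatrix, annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Annotation table reordered to match ``expr.sample_ids`` exactly."""
    by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in expr.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"annotations missing for samples: {missing[:5]}")
    rows = [dataclasses.asdict(by_id[s]) for s in expr.sample_ids]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).set_index("sample_id")
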