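"""Expression and clinical I/O, and per-gene z-score normalization.

The whole pipeline runs on z-transformed expression: each gene's (log2)
values are centered and scaled across samples so that every gene has mean 0
and sample standard deviation 1. Each cohort is normalized within itself —
a frozen signature applied to a new cohort is evaluated on that cohort's own
z-scores, the only scale comparable across platforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ZMatrix",
    "ClinicalTable",
    "load_expression",
    "load_clinical",
    "align_samples",
    "normalize",
    "GOOD",
    "POOR",
]

#: Canonical prognosis-class labels: "poor" = event (death) observed.
GOOD = "good"
POOR = "poor"

_Z_TOL = 1e-9


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values, raw-intensity or log2 scale.

    ``data`` is a DataFrame with gene symbols as index and sample ids as
    columns; ``log2`` flags whether values are already log2-transformed.
    """

    data: pd.DataFrame
    log2: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite expression value for gene "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ZMatrix:
    """Per-gene z-scores: each row has mean 0 and sample sd 1 (ddof=1)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if vals.size == 0:
            return
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        bad = np.flatnonzero(
            (np.abs(mean) > _Z_TOL) | (np.abs(sd - 1.0) > 1e-6)
        )
        if bad.size:
            raise ValueError(
                f"row {self.data.index[bad[0]]!r} is not z-normalized "
                f"(mean={mean[bad[0]]:.3g}, sd={sd[bad[0]]:.6g})"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ClinicalTable:
    """Per-sample survival and prognosis annotations.

    Required columns: ``time_months`` (positive, finite) and ``event``
    (0 censored / 1 death). Optional: ``label`` with values ``good``/``poor``
    and any number of additional covariate columns. Index is the sample id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        for col in ("time_months", "event"):
            if col not in df.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        t = df["time_months"].to_numpy(dtype=float)
        if not (np.isfinite(t).all() and (t > 0).all()):
            raise ValueError("time_months must be finite and > 0")
        ev = set(df["event"].tolist())
        if not ev <= {0, 1}:
            raise ValueError(f"event values must be 0/1, got {sorted(ev - {0, 1})}")
        if "label" in df.columns:
            lab = set(df["label"].dropna())
            if not lab <= {GOOD, POOR}:
                raise ValueError(f"labels must be good/poor, got {sorted(lab)}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time_months"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    @property
    def labels(self) -> pd.Series:
        if "label" not in self.data.columns:
            raise ValueError("clinical table has no prognosis label column")
        return self.data["label"]

    def subset(self, samples) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


def load_expression(path: str | Path, log2: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbol, header = samples)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for gene in df.index:
        row = df.loc[gene]
        coerced = pd.to_numeric(row, errors="coerce")
        bad = coerced.index[coerced.isna() & row.notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric expression value {row[bad[0]]!r} "
                f"for gene {gene!r}, sample {bad[0]!r}"
            )
        if row.isna().any():
            sample = row.index[row.isna()][0]
            raise ValueError(
                f"{path}: missing expression value for gene {gene!r}, "
                f"sample {sample!r}"
            )
    return ExpressionMatrix(df.astype(float), log2=log2)


def load_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns ``sample, time_months, event, ...``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: clinical table lacks a 'sample' column")
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def align_samples(
    expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Reconcile the two sample sets: keep the intersection, warn about drops.

    Column order of the expression matrix is preserved for shared samples.
    """
    shared = [s for s in expr.samples if s in set(clinical.samples)]
    extra_clin = sorted(set(clinical.samples) - set(shared))
    extra_expr = sorted(set(expr.samples) - set(shared))
    if extra_clin:
        warnings.warn(
            f"{len(extra_clin)} clinical sample(s) absent from expression "
            f"dropped: {extra_clin[:5]}{'...' if len(extra_clin) > 5 else ''}"
        )
    if extra_expr:
        warnings.warn(
            f"{len(extra_expr)} expression sample(s) without clinical data "
            f"dropped: {extra_expr[:5]}{'...' if len(extra_expr) > 5 else ''}"
        )
    if not shared:
        raise ValueError("no samples shared between expression and clinical data")
    return (
        ExpressionMatrix(expr.data[shared], log2=expr.log2),
        clinical.subset(shared),
    )


def normalize(expr: ExpressionMatrix, already_log2: bool | None = None) -> ZMatrix:
    """Log2-transform (if raw) then z-score each gene across samples.

    Uses the sample standard deviation (n-1 denominator). Genes with zero
    variance are dropped with a logged report: their z-score is undefined.

    Parameters
    ----------
    expr
        Input matrix; must be strictly positive if a log2 transform is needed.
    already_log2
        Overrides ``expr.log2`` when given.
    """
    if already_log2 is None:
        already_log2 = expr.log2
    vals = expr.data.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene to z-normalize")
    if not already_log2:
        if (vals <= 0).any():
            i, j = np.argwhere(vals <= 0)[0]
            raise ValueError(
                f"non-positive value {vals[i, j]!r} for gene "
                f"{expr.data.index[i]!r} cannot be log2-transformed"
            )
        vals = np.log2(vals)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = list(expr.data.index[~keep][:10])
        logger.warning(
            "dropping %d zero-variance gene(s): %s%s",
            n_dropped, dropped, "..." if n_dropped > 10 else "",
        )
    z = (vals[keep] - mean[keep]) / sd[keep]
    return ZMatrix(
        pd.DataFrame(z, index=expr.data.index[keep], columns=expr.data.columns)
    )
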