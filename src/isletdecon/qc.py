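"""Cell-level quality control and log-normalization.

Three threshold filters (features detected, total counts, percent
mitochondrial counts) with inclusive range endpoints, followed by a
residual-based filter that drops cells whose total count is not predictive of
their feature count, then Seurat-style LogNormalize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_MITO_PREFIX = "mt-"


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive acceptance ranges for the three per-cell criteria."""

    n_feature_range: tuple[int, int] = (500, 3000)
    n_count_range: tuple[int, int] = (1000, 30000)
    pct_mito_range: tuple[float, float] = (0.0, 30.0)
    residual_sd_k: float = 3.0

    def __post_init__(self) -> None:
        for lo, hi in (self.n_feature_range, self.n_count_range, self.pct_mito_range):
            if lo > hi:
                raise ValidationError(f"range lower bound {lo} exceeds upper bound {hi}")
        if self.residual_sd_k <= 0:
            raise ValidationError("residual_sd_k must be positive")


@dataclass
class QCReport:
    """Per-cell pass/fail flags per criterion plus before/after counts."""

    table: pd.DataFrame  # columns: n_feature, n_count, pct_mito, pass_* flags
    n_before: int
    n_after: int


def mito_mask(gene_names, prefix: str = DEFAULT_MITO_PREFIX) -> np.ndarray:
    """Boolean mask of mitochondrial genes identified by name prefix."""
    return np.array([str(g).lower().startswith(prefix.lower()) for g in gene_names])


def cell_metrics(counts: np.ndarray, mito: np.ndarray | None = None) -> pd.DataFrame:
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    n_count = counts.sum(axis=1)
    n_feature = (counts > 0).sum(axis=1)
    if mito is None:
        mito = np.zeros(counts.shape[1], dtype=bool)
    mito_counts = counts[:, np.asarray(mito, dtype=bool)].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_count > 0, 100.0 * mito_counts / np.maximum(n_count, 1e-300), 0.0)
    return pd.DataFrame(
        {"n_count": n_count, "n_feature": n_feature, "pct_mito": pct_mito}
    )


def threshold_filter(
    counts: np.ndarray,
    mito: np.ndarray | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[QCReport, np.ndarray]:
    """Keep exactly the cells inside all three closed acceptance ranges.

    A cell with zero total counts has pct_mito defined as 0 (it is removed by
    the count range anyway).  Removing every cell is a warning, not an error.
    """
    counts = np.asarray(counts)
    metrics = cell_metrics(counts, mito)
    flo, fhi = thresholds.n_feature_range
    clo, chi = thresholds.n_count_range
    mlo, mhi = thresholds.pct_mito_range
    metrics["pass_n_feature"] = (metrics.n_feature >= flo) & (metrics.n_feature <= fhi)
    metrics["pass_n_count"] = (metrics.n_count >= clo) & (metrics.n_count <= chi)
    metrics["pass_pct_mito"] = (metrics.pct_mito >= mlo) & (metrics.pct_mito <= mhi)
    metrics["pass_overall"] = (
        metrics.pass_n_feature & metrics.pass_n_count & metrics.pass_pct_mito
    )
    keep = metrics["pass_overall"].to_numpy()
    if keep.sum() == 0:
        warnings.warn("threshold_filter removed every cell", stacklevel=2)
    report = QCReport(table=metrics, n_before=len(metrics), n_after=int(keep.sum()))
    return report, counts[keep]


def residual_filter(
    n_count: np.ndarray, n_feature: np.ndarray, k: float = 3.0
) -> np.ndarray:
    """Keep cells whose nFeature ~ nCount OLS residual is within k SD of 0.

    With ordinary least squares the mean residual is 0 by construction; the SD
    uses the n-1 denominator.  Perfectly collinear cells (zero residual
    variance) are all kept, as are all cells when fewer than 3 are given.
    """
    n_count = np.asarray(n_count, dtype=float)
    n_feature = np.asarray(n_feature, dtype=float)
    if n_count.shape != n_feature.shape:
        raise ValidationError("n_count and n_feature must have the same length")
    n = n_count.size
    if n < 3:
        warnings.warn("residual_filter needs >= 3 cells; keeping all", stacklevel=2)
        return np.ones(n, dtype=bool)
    if np.allclose(n_count, n_count[0]):
        # degenerate predictor: fall back to intercept-only fit
        resid = n_feature - n_feature.mean()
    else:
        slope, intercept = np.polyfit(n_count, n_feature, 1)
        resid = n_feature - (slope * n_count + intercept)
    sd = resid.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.ones(n, dtype=bool)
    return np.abs(resid - resid.mean()) <= k * sd


def log_normalize(counts: np.ndarray, scale_factor: float = 1e4) -> np.ndarray:
    """Seurat LogNormalize: ln(1 + scale_factor * count / cell_total).

    Cells with zero total map to all-zero rows.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(totals > 0, scale_factor * counts / np.maximum(totals, 1e-300), 0.0)
    return np.log1p(scaled)


def qc_pipeline(
    counts: np.ndarray,
    gene_names,
    thresholds: QCThresholds = QCThresholds(),
    mito_prefix: str = DEFAULT_MITO_PREFIX,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold filter, then residual filter on the survivors.

    Returns the boolean keep mask over the original cells and the per-cell QC
    table (flags for every criterion, including the residual filter).
    """
    counts = np.asarray(counts)
    mito = mito_mask(gene_names, mito_prefix)
    report, _ = threshold_filter(counts, mito, thresholds)
    table = report.table.copy()
    keep = table["pass_overall"].to_numpy().copy()
    if keep.sum() >= 3:
        sub = table.loc[keep]
        res_keep = residual_filter(
            sub["n_count"].to_numpy(), sub["n_feature"].to_numpy(), thresholds.residual_sd_k
        )
        table["pass_residual"] = False
        table.loc[sub.index[res_keep], "pass_residual"] = True
        keep = keep & table["pass_residual"].to_numpy()
    else:
        table["pass_residual"] = keep
    table["keep"] = keep
    return keep, table
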