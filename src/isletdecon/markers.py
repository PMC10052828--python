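"""Marker gene detection between cell groups by Wilcoxon rank-sum test.

Per gene: two-sided rank-sum p (normal approximation with tie correction),
average log fold change as the difference of mean log-normalized values, and
the fraction of expressing cells per group.  A gene is reported significant
for the focal (higher-expressing) group when the log-FC, percent-expressed
and Bonferroni-adjusted p thresholds are all met.  Default thresholds follow
the two detection settings used in practice: log-FC >= 0.25 with >= 25% of
cells expressing for cell-type markers, and log-FC >= 0.1 with Bonferroni
p < 0.01 for subtype profiles.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def rank_sum_markers(
    expr: np.ndarray,
    labels: Sequence,
    group_a,
    group_b,
    gene_names: Sequence[str] | None = None,
    lfc_min: float = 0.25,
    min_pct: float = 0.25,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Two-group marker table over all genes.

    ``avg_log_fc`` is mean(log values in a) - mean(log values in b) (base
    follows the input normalization, natural log for LogNormalize output).
    The Bonferroni multiplier is the number of genes tested.  Significance is
    one-directional: the focal group a must be the higher-expressing one.
    """
    if correction != "bonferroni":
        raise ValidationError(f"unsupported correction {correction!r}")
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    in_a = labels == group_a
    in_b = labels == group_b
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValidationError("both groups must be non-empty")
    if min(in_a.sum(), in_b.sum()) < 3:
        warnings.warn("group smaller than 3 cells: p-values are degenerate", stacklevel=2)
    a, b = expr[in_a], expr[in_b]
    n_genes = expr.shape[1]
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(n_genes)]

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-tied genes produce nan p, handled below
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance (all-tied) genes are null

    avg_log_fc = a.mean(axis=0) - b.mean(axis=0)
    pct_a = (a > 0).mean(axis=0)
    pct_b = (b > 0).mean(axis=0)
    p_adj = np.minimum(1.0, p * n_genes)
    significant = (
        (avg_log_fc >= lfc_min)
        & (np.maximum(pct_a, pct_b) >= min_pct)
        & (p_adj < alpha)
    )
    return pd.DataFrame(
        {
            "gene": list(gene_names),
            "group_a": group_a,
            "group_b": group_b,
            "avg_log_fc": avg_log_fc,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": significant,
        }
    ).set_index("gene")


def subtype_profiles(
    expr: np.ndarray,
    subtype_labels: Sequence,
    gene_names: Sequence[str] | None = None,
    lfc_min: float = 0.1,
    min_pct: float = 0.0,
    alpha: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest overexpression profiles per subtype.

    Each subtype is contrasted against all other cells of the parent type; a
    gene may appear in several subtype sets.  Singleton subtypes are skipped
    with a warning.
    """
    labels = np.asarray(subtype_labels)
    subtypes = pd.unique(labels)
    if len(subtypes) < 2:
        raise ValidationError("need at least 2 subtypes")
    out: dict[str, pd.DataFrame] = {}
    for st in subtypes:
        if (labels == st).sum() < 2:
            warnings.warn(f"singleton subtype {st!r} skipped", stacklevel=2)
            continue
        rest = np.where(labels == st, str(st), "__rest__")
        out[str(st)] = rank_sum_markers(
            expr,
            rest,
            str(st),
            "__rest__",
            gene_names=gene_names,
            lfc_min=lfc_min,
            min_pct=min_pct,
            alpha=alpha,
        )
    return out


def overexpressed_sets(profiles: Mapping[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Significant gene set per subtype from :func:`subtype_profiles` output."""
    return {st: set(tab.index[tab.significant]) for st, tab in profiles.items()}
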