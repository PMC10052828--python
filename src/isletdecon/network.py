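"""Weighted co-expression network analysis on bulk samples.

Pipeline: TMM-style normalization of bulk counts, gene-wise rank-based
inverse normal transform, biweight midcorrelation between all gene pairs,
unsigned soft-thresholded adjacency ``|cor|^power`` (default power 8, chosen
for a scale-free topology index above 0.9), topological overlap (TOM),
average-linkage module detection on 1 - TOM, module eigengenes (first
principal components), Pearson module-trait correlation with
Benjamini-Hochberg FDR, module membership (kME), intramodular connectivity
k_within, and differential connectivity between cohorts

    kDiff = (k_a - k_b) / (k_a + k_b)

where k_a and k_b are cohort-specific k_within values recomputed from each
cohort's own samples under the shared module labels; |kDiff| > 0.5 (strict)
flags a gene as differentially connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# Normalization


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (edgeR-style, sample x gene).

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean across samples.  M (log ratio) and A (log abundance)
    values over genes positive in both samples are doubly trimmed (30% on M,
    5% on A) and averaged with inverse asymptotic-variance weights.  Factors
    are normalized to multiply to 1 in geometric mean; a factor below 1 marks
    a library monopolized by a few high-count genes.
    """
    if counts.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    lib = counts.sum(axis=1).astype(float)
    if (lib <= 0).any():
        raise ValidationError("a sample has zero total counts")
    frac = counts.div(lib, axis=0)
    uq = frac.apply(lambda r: np.quantile(r[r > 0], 0.75) if (r > 0).any() else 0.0, axis=1)
    if reference is None:
        reference = (uq - uq.mean()).abs().idxmin()
    ref = counts.loc[reference].astype(float)
    ref_lib = lib[reference]

    factors = {}
    for s in counts.index:
        if s == reference:
            factors[s] = 1.0
            continue
        obs = counts.loc[s].astype(float)
        keep = (obs > 0) & (ref > 0)
        if keep.sum() < 2:
            factors[s] = 1.0
            continue
        y_s, y_r = obs[keep].to_numpy(), ref[keep].to_numpy()
        p_s, p_r = y_s / lib[s], y_r / ref_lib
        m = np.log2(p_s / p_r)
        a = 0.5 * np.log2(p_s * p_r)
        w = (lib[s] - y_s) / (lib[s] * y_s) + (ref_lib - y_r) / (ref_lib * y_r)
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        mask = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi) & (w > 0)
        if mask.sum() == 0:
            factors[s] = 1.0
            continue
        mbar = np.sum(m[mask] / w[mask]) / np.sum(1.0 / w[mask])
        factors[s] = float(2**mbar)
    f = pd.Series(factors).loc[counts.index]
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    return f


def normalize_bulk(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM effective library sizes (+0.5 prior)."""
    factors = tmm_factors(counts)
    eff = counts.sum(axis=1) * factors
    cpm = counts.div(eff, axis=0) * 1e6
    return np.log2(cpm + prior)


def inverse_normal_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise rank-based inverse normal scores with the Blom offset.

    ``Phi^{-1}((r - 3/8) / (n + 1/4))`` with average ranks for ties; constant
    genes map to all zeros with a warning.  Being rank-based, the transform
    is invariant under any monotone per-gene transformation.
    """
    if expr.shape[0] < 3:
        raise ValidationError("need at least 3 samples")
    n = expr.shape[0]
    out = np.empty(expr.shape)
    constant = []
    values = expr.to_numpy()
    for j in range(expr.shape[1]):
        col = values[:, j]
        if np.allclose(col, col[0]):
            out[:, j] = 0.0
            constant.append(expr.columns[j])
            continue
        r = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))
    if constant:
        warnings.warn(f"{len(constant)} constant gene(s) set to zero scores", stacklevel=2)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# Correlation and adjacency


def bicor_matrix(expr: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Biweight midcorrelation between all gene pairs (samples x genes).

    ``u_i = (x_i - median) / (9 * MAD)``; weights ``(1 - u^2)^2`` inside
    |u| < 1 and zero outside.  Genes with MAD = 0 fall back to Pearson
    (mean/SD standardization) with a warning.
    """
    is_df = isinstance(expr, pd.DataFrame)
    X = expr.to_numpy(dtype=float) if is_df else np.asarray(expr, dtype=float)
    if X.shape[0] < 4:
        raise ValidationError("need at least 4 samples")
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    zero_mad = mad == 0
    if zero_mad.any():
        warnings.warn(
            f"{int(zero_mad.sum())} gene(s) with zero MAD: Pearson fallback", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * np.where(zero_mad, 1.0, mad))
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = (X - med) * w
    # Pearson fallback columns: plain centered values
    if zero_mad.any():
        xc = X - X.mean(axis=0)
        xt[:, zero_mad] = xc[:, zero_mad]
    norms = np.sqrt((xt**2).sum(axis=0))
    bad = norms == 0
    norms = np.where(bad, 1.0, norms)
    xn = xt / norms
    c = xn.T @ xn
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    if bad.any():
        c[bad, :] = 0.0
        c[:, bad] = 0.0
        np.fill_diagonal(c, 1.0)
    if is_df:
        return pd.DataFrame(c, index=expr.columns, columns=expr.columns)
    return c


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    if x.size < 4:
        raise ValidationError("need at least 4 samples")
    c = bicor_matrix(np.column_stack([x, y]))
    return float(c[0, 1])


def adjacency_matrix(cor: pd.DataFrame | np.ndarray, power: float = 8.0):
    """Unsigned soft-thresholded adjacency ``|cor|^power`` with zero diagonal."""
    a = np.abs(np.asarray(cor, dtype=float)) ** power
    np.fill_diagonal(a, 0.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(a, index=cor.index, columns=cor.columns)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R² of the log-log connectivity distribution fit.

    Bins connectivity into equal-width bins, regresses log10 frequency on
    log10 mean connectivity per bin; the index is R² when the slope is
    negative and -R² otherwise.  Returns ``(signed_r2, slope)``.
    """
    k = np.asarray(k, dtype=float)
    if k.max() == k.min():
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, centers = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        freq.append(mask.mean())
        centers.append(k[mask].mean())
    freq = np.asarray(freq)
    centers = np.asarray(centers)
    ok = (freq > 0) & (centers > 0)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    lx, ly = np.log10(centers[ok]), np.log10(freq[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = ((ly - pred) ** 2).sum()
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    cor: pd.DataFrame | np.ndarray,
    candidate_powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.9,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free topology index reaches the target.

    Powers <= 0 are excluded (adjacency would be all ones).  If no candidate
    reaches the target, the power maximizing the signed R² is returned with a
    warning.
    """
    powers = [p for p in candidate_powers if p > 0]
    if not powers:
        raise ValidationError("no positive candidate powers")
    rows = []
    for p in powers:
        a = adjacency_matrix(cor, power=p)
        k = np.asarray(a).sum(axis=0)
        signed_r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": p, "signed_r2": signed_r2, "slope": slope, "mean_k": k.mean()})
    table = pd.DataFrame(rows)
    ok = table[table.signed_r2 >= r2_target]
    if len(ok):
        power = int(ok.power.iloc[0])
    else:
        if table.signed_r2.notna().any():
            power = int(table.loc[table.signed_r2.idxmax(), "power"])
        else:
            power = powers[0]
        warnings.warn(
            f"no power reached scale-free R² {r2_target}; using {power}", stacklevel=2
        )
    return power, table


def tom_matrix(adjacency: pd.DataFrame | np.ndarray):
    """Unsigned topological overlap.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj``; the diagonal is 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValidationError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    l = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


# ---------------------------------------------------------------------------
# Modules


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 5,
    cut_height: float = 0.995,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters below ``min_module_size`` are labelled "unassigned".  Module ids
    M1, M2, ... are assigned by decreasing size; labels are deterministic.
    """
    genes = list(tom.index)
    if len(genes) < min_module_size:
        return pd.Series(UNASSIGNED, index=genes, name="module")
    d = 1.0 - np.asarray(tom, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")
    sizes = pd.Series(flat).value_counts()
    keep = sizes[sizes >= min_module_size]
    order = keep.sort_values(ascending=False).index
    # size-desc with cluster-id tiebreak for determinism
    order = sorted(order, key=lambda c: (-keep[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(order)}
    labels = [rename.get(c, UNASSIGNED) for c in flat]
    return pd.Series(labels, index=genes, name="module")


def eigengene(expr: pd.DataFrame, module_labels: pd.Series) -> pd.DataFrame:
    """First-principal-component eigengene per module (sample x module).

    Genes are standardized before the SVD; the eigengene sign is aligned to
    correlate positively with the module's mean expression profile and it is
    scaled to unit variance.  Degenerate modules fall back to the mean
    profile with a warning.
    """
    modules = sorted(m for m in module_labels.unique() if m != UNASSIGNED)
    cols = {}
    for m in modules:
        genes = module_labels.index[module_labels == m]
        sub = expr[genes].to_numpy(dtype=float)
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        ok = sd > 0
        if ok.sum() < 2:
            warnings.warn(f"module {m} is degenerate; using mean profile", stacklevel=2)
            profile = sub.mean(axis=1)
        else:
            z = (sub[:, ok] - mean[ok]) / sd[ok]
            u, s, _ = np.linalg.svd(z, full_matrices=False)
            profile = u[:, 0] * s[0]
        mean_profile = sub.mean(axis=1)
        if np.std(profile) == 0:
            warnings.warn(f"module {m} eigengene is constant", stacklevel=2)
            cols[m] = np.zeros(expr.shape[0])
            continue
        if np.corrcoef(profile, mean_profile)[0, 1] < 0:
            profile = -profile
        cols[m] = (profile - profile.mean()) / profile.std(ddof=1)
    return pd.DataFrame(cols, index=expr.index)


def module_trait(
    eigengenes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pearson module-trait correlations with Benjamini-Hochberg FDR.

    Missing phenotype values are dropped pairwise; constant phenotypes are
    excluded with a warning.  Significant iff q < ``fdr``.
    """
    rows = []
    for trait in phenotypes.columns:
        y_all = phenotypes[trait]
        for m in eigengenes.columns:
            x_all = eigengenes[m]
            mask = x_all.notna() & y_all.notna()
            if mask.sum() < 4:
                warnings.warn(f"fewer than 4 paired samples for {m} x {trait}", stacklevel=2)
                continue
            x, y = x_all[mask], y_all[mask]
            if np.std(y) == 0 or np.std(x) == 0:
                warnings.warn(f"constant values for {m} x {trait}: excluded", stacklevel=2)
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"module": m, "phenotype": trait, "pearson_r": r, "p_value": p})
    result = pd.DataFrame(rows)
    if result.empty:
        return result.reindex(
            columns=["module", "phenotype", "pearson_r", "p_value", "fdr_q", "significant"]
        )
    _, q, _, _ = multipletests(result.p_value, method="fdr_bh")
    result["fdr_q"] = q
    result["significant"] = result.fdr_q < fdr
    return result


def module_membership(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: Pearson correlation of each gene profile with each eigengene."""
    genes = expr.columns
    out = np.empty((len(genes), eigengenes.shape[1]))
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    xs = xc.std(axis=0, ddof=0)
    e = eigengenes.to_numpy(dtype=float)
    ec = e - e.mean(axis=0)
    es = ec.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (xc.T @ ec) / expr.shape[0] / np.outer(xs, es)
    out = np.clip(out, -1.0, 1.0)
    return pd.DataFrame(out, index=genes, columns=eigengenes.columns)


def gene_trait_correlations(expr: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each gene with each phenotype."""
    out = {}
    for trait in phenotypes.columns:
        y = phenotypes[trait].to_numpy(dtype=float)
        x = expr.to_numpy(dtype=float)
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            out[trait] = np.where(denom > 0, xc.T @ yc / np.maximum(denom, 1e-300), np.nan)
    return pd.DataFrame(out, index=expr.columns)


def k_within(adjacency: pd.DataFrame, module_labels: pd.Series) -> pd.Series:
    """Intramodular connectivity: adjacency sum to same-module genes.

    Unassigned genes get their connectivity over the unassigned set (callers
    should treat those as flagged, not as module statistics).
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    genes = list(adjacency.index)
    labels = module_labels.loc[genes].to_numpy()
    out = np.zeros(len(genes))
    for m in pd.unique(labels):
        idx = np.flatnonzero(labels == m)
        out[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    return pd.Series(out, index=genes, name="k_within")


def kdiff(k_a: np.ndarray, k_b: np.ndarray) -> np.ndarray:
    """Normalized connectivity difference (k_a - k_b) / (k_a + k_b).

    Undefined (NaN) where k_a + k_b = 0.
    """
    k_a = np.asarray(k_a, dtype=float)
    k_b = np.asarray(k_b, dtype=float)
    total = k_a + k_b
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(total > 0, (k_a - k_b) / np.where(total > 0, total, 1.0), np.nan)


def differential_connectivity_from_adjacency(
    adj_a: pd.DataFrame,
    adj_b: pd.DataFrame,
    module_labels: pd.Series,
    flag_threshold: float = 0.5,
) -> pd.DataFrame:
    """kDiff per gene from two cohort adjacencies under shared module labels.

    ``flagged`` requires strictly |kDiff| > ``flag_threshold``; genes with
    zero total connectivity are marked undefined instead of flagged.
    """
    if list(adj_a.index) != list(adj_b.index):
        raise ValidationError("cohort adjacencies must share the same gene set")
    k_a = k_within(adj_a, module_labels)
    k_b = k_within(adj_b, module_labels)
    kd = kdiff(k_a.to_numpy(), k_b.to_numpy())
    out = pd.DataFrame(
        {
            "module": module_labels.loc[adj_a.index].to_numpy(),
            "k_a": k_a,
            "k_b": k_b,
            "k_diff": kd,
        }
    )
    out["undefined"] = ~np.isfinite(kd)
    out["flagged"] = np.where(out.undefined, False, np.abs(kd) > flag_threshold)
    return out


def differential_connectivity(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    module_labels: pd.Series,
    power: float = 8.0,
    flag_threshold: float = 0.5,
) -> pd.DataFrame:
    """Recompute cohort adjacencies (bicor^power) and compare connectivity.

    Both cohorts need >= 4 samples and the same gene set; module labels come
    from the all-sample network and are shared.
    """
    if list(expr_a.columns) != list(expr_b.columns):
        raise ValidationError("cohorts must share the same gene set")
    if expr_a.shape[0] < 4 or expr_b.shape[0] < 4:
        raise ValidationError("each cohort needs at least 4 samples")
    adj_a = adjacency_matrix(bicor_matrix(expr_a), power=power)
    adj_b = adjacency_matrix(bicor_matrix(expr_b), power=power)
    return differential_connectivity_from_adjacency(
        adj_a, adj_b, module_labels, flag_threshold=flag_threshold
    )


def edge_list(adjacency: pd.DataFrame, min_weight: float = 0.0) -> pd.DataFrame:
    """Long-format (gene1, gene2, adjacency) table for visualization."""
    a = np.asarray(adjacency, dtype=float)
    genes = list(adjacency.index)
    iu = np.triu_indices(len(genes), k=1)
    weights = a[iu]
    keep = weights >= min_weight
    return pd.DataFrame(
        {
            "gene1": [genes[i] for i in iu[0][keep]],
            "gene2": [genes[j] for j in iu[1][keep]],
            "adjacency": weights[keep],
        }
    )


@dataclass
class CoexpressionNetwork:
    """Bundled outputs of the all-sample network construction."""

    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    power: float
    module_labels: pd.Series
    eigengenes: pd.DataFrame
    k_within: pd.Series


def build_network(
    expr: pd.DataFrame,
    power: float = 8.0,
    min_module_size: int = 5,
    cut_height: float = 0.995,
) -> CoexpressionNetwork:
    """Standard-normal transform -> bicor -> adjacency -> TOM -> modules."""
    scores = inverse_normal_transform(expr)
    cor = bicor_matrix(scores)
    adj = adjacency_matrix(cor, power=power)
    tom = tom_matrix(adj)
    labels = detect_modules(tom, min_module_size=min_module_size, cut_height=cut_height)
    eg = eigengene(scores, labels)
    kw = k_within(adj, labels)
    return CoexpressionNetwork(
        correlation=cor, adjacency=adj, tom=tom, power=power,
        module_labels=labels, eigengenes=eg, k_within=kw,
    )
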