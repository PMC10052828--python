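"""Beta-hurdle attribution of gene expression to cell types.

Single-cell expression of a gene within a cell type is modelled as a hurdle:
a point mass at zero plus a beta distribution on the open unit interval,
parameterized by Pr(Dropout), alpha and beta.  Shapes are chosen by maximum
goodness of fit — minimizing the two-sided Kolmogorov-Smirnov distance between
the empirical CDF of the nonzero values and the theoretical beta CDF.
Pr(Dropout) is then iterated over [0, 1]: a candidate d treats fraction d of
the observed zeros as technical dropout and censors them from the data side,
comparing the retained sample (true zeros + nonzero values) against the beta;
the d minimizing the KS distance wins, ties broken toward more dropout.  A
continuous beta cannot absorb a retained point mass at zero, so zeros that a
beta explains poorly are attributed to dropout — typically d = 1.

From the fitted shapes, a cell type's expected expression is
E[Y] = 1 / (1 + beta/alpha) = alpha / (alpha + beta); multiplying by the
number of cells of that type and normalizing over cell types yields the
relative contribution Q.  Genes whose target-cell-type Q clears a threshold
(default 0.8) in *every* cohort are called cell-type specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, ValidationError

RESCALE_EPS = 1e-6
DEFAULT_N_MIN_NONZERO = 20
DEFAULT_SHAPE_BOUNDS = (0.01, 100.0)


@dataclass(frozen=True)
class BetaHurdleFit:
    """Fitted hurdle parameters for one gene x cell type x cohort."""

    alpha: float
    beta_: float
    pr_dropout: float
    zero_fraction: float
    ks_distance: float
    n_cells: int
    n_nonzero: int

    @property
    def pi0(self) -> float:
        """True-zero point mass implied by the dropout attribution."""
        return self.zero_fraction * (1.0 - self.pr_dropout)


def rescale_to_unit(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Map non-negative expression onto the open unit interval.

    ``v' = v / (max(v) * (1 + eps))`` — monotone, scale-free, zeros stay zero.
    Returns the rescaled values and the scale used.  All-zero input raises
    (the gene is skipped upstream).
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValidationError("expression values must be non-negative")
    vmax = values.max() if values.size else 0.0
    if vmax <= 0:
        raise ValidationError("all-zero input cannot be rescaled")
    scale = vmax * (1.0 + RESCALE_EPS)
    return values / scale, scale


def _ks_distance(sorted_values: np.ndarray, cdf: np.ndarray) -> float:
    """Two-sided sup distance for pre-sorted data (right-continuous ECDF)."""
    n = sorted_values.size
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return float(max((hi - cdf).max(), (cdf - lo).max()))


def fit_beta_ks(
    nonzero_values: np.ndarray,
    n_grid: int = 8,
    bounds: tuple[float, float] = DEFAULT_SHAPE_BOUNDS,
    n_min: int = DEFAULT_N_MIN_NONZERO,
    refine: bool = True,
) -> tuple[float, float, float]:
    """KS-minimizing beta shapes for values on the open unit interval.

    Search: coarse log-spaced grid over ``bounds``² refined by Nelder-Mead
    from the best grid point (in log-shape space).  The returned KS distance
    never exceeds the distance at any evaluated candidate.
    """
    x = np.sort(np.asarray(nonzero_values, dtype=float))
    if x.size < n_min:
        raise ValidationError(f"need >= {n_min} nonzero values, got {x.size}")
    if x[0] <= 0 or x[-1] >= 1:
        raise ValidationError("values must lie strictly inside (0, 1)")
    n = x.size
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n

    best: list = [np.inf, None]  # (ks, (alpha, beta))

    def evaluate(a: float, b: float) -> float:
        cdf = stats.beta.cdf(x, a, b)
        ks = float(max((hi - cdf).max(), (cdf - lo).max()))
        if ks < best[0]:
            best[0], best[1] = ks, (a, b)
        return ks

    grid = np.geomspace(bounds[0], bounds[1], n_grid)
    for a in grid:
        for b in grid:
            evaluate(a, b)

    if refine:
        log_lo, log_hi = np.log(bounds[0]), np.log(bounds[1])

        def objective(log_ab: np.ndarray) -> float:
            la, lb = np.clip(log_ab, log_lo, log_hi)
            return evaluate(float(np.exp(la)), float(np.exp(lb)))

        optimize.minimize(
            objective,
            np.log(best[1]),
            method="Nelder-Mead",
            options={"maxfev": 200, "xatol": 1e-4, "fatol": 1e-6},
        )
    a, b = best[1]
    return float(a), float(b), float(best[0])


def fit_hurdle(
    values: np.ndarray,
    dropout_grid_step: float = 0.01,
    n_min_nonzero: int = DEFAULT_N_MIN_NONZERO,
    n_grid: int = 8,
    bounds: tuple[float, float] = DEFAULT_SHAPE_BOUNDS,
) -> BetaHurdleFit | None:
    """Fit the hurdle model to values (zeros included) on [0, 1).

    Returns ``None`` (with a warning) when the gene is all-zero or has fewer
    than ``n_min_nonzero`` nonzero values in this cell type — a low-support
    skip, not an error.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any() or (values >= 1).any():
        raise ValidationError("values must lie in [0, 1); rescale first")
    nonzero = values[values > 0]
    n = values.size
    n_nz = nonzero.size
    if n_nz == 0:
        warnings.warn("all-zero gene: no fit", stacklevel=2)
        return None
    if n_nz < n_min_nonzero:
        warnings.warn(f"only {n_nz} nonzero values: fit skipped", stacklevel=2)
        return None
    alpha, beta_, ks_nz = fit_beta_ks(nonzero, n_grid=n_grid, bounds=bounds)
    n0 = n - n_nz
    zero_fraction = n0 / n
    if n0 == 0:
        return BetaHurdleFit(alpha, beta_, 1.0, 0.0, ks_nz, n, n_nz)

    xs = np.sort(nonzero)
    cdf = stats.beta.cdf(xs, alpha, beta_)
    d_grid = np.round(np.arange(0.0, 1.0 + dropout_grid_step / 2, dropout_grid_step), 10)
    # retained-zero mass after censoring fraction d of the observed zeros
    w0 = n0 * (1.0 - d_grid) / (n - n0 * d_grid)
    frac_hi = np.arange(1, n_nz + 1) / n_nz
    frac_lo = np.arange(0, n_nz) / n_nz
    emp_hi = w0[:, None] + (1.0 - w0)[:, None] * frac_hi  # ECDF just after each x_i
    emp_lo = w0[:, None] + (1.0 - w0)[:, None] * frac_lo  # ECDF just before each x_i
    dev = np.maximum(np.abs(emp_hi - cdf), np.abs(emp_lo - cdf)).max(axis=1)
    ks_by_d = np.maximum(dev, w0)  # the beta cannot match the zero jump
    ks_min = float(ks_by_d.min())
    candidates = np.flatnonzero(ks_by_d <= ks_min + 1e-12)
    d_best = float(d_grid[candidates[-1]])  # ties broken toward more dropout
    return BetaHurdleFit(alpha, beta_, d_best, zero_fraction, ks_min, n, n_nz)


def hurdle_cdf(x: np.ndarray, fit: BetaHurdleFit) -> np.ndarray:
    """Mixture CDF: pi0 point mass at 0 plus (1 - pi0) beta weight.

    The CDF at 0 equals pi0 = zero_fraction * (1 - pr_dropout) exactly.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, 0.0, fit.pi0 + (1.0 - fit.pi0) * stats.beta.cdf(x, fit.alpha, fit.beta_))
    return out


def expected_value(fit: BetaHurdleFit, mode: str = "plain") -> float:
    """Expected expression of one cell type under the fitted model.

    ``"plain"`` (default): the plain beta mean ``1 / (1 + beta/alpha)``,
    equal to alpha / (alpha + beta).  ``"mixture"``: downweighted by the
    implied true-zero mass, ``(1 - pi0) * alpha / (alpha + beta)`` — the two
    coincide when all zeros are attributed to dropout.
    """
    e = 1.0 / (1.0 + fit.beta_ / fit.alpha)
    if mode == "plain":
        return e
    if mode == "mixture":
        return (1.0 - fit.pi0) * e
    raise ConfigurationError(f"unknown expected_value mode {mode!r}")


@dataclass
class ContributionTable:
    """Per-cohort relative contributions Q and the raw E[Y] * N terms."""

    cohort: str
    q: pd.DataFrame  # gene x cell type, rows sum to 1 where defined
    terms: pd.DataFrame  # gene x cell type, E[Y] * N
    undefined: pd.Index  # genes with all-zero terms


def contribution_table(
    fits: Mapping[str, Mapping[str, BetaHurdleFit | None]],
    cell_counts: Mapping[str, int],
    cohort: str = "",
    expected_value_mode: str = "plain",
) -> ContributionTable:
    """Relative contribution Q(g, ct) = E[Y_g,ct] * N_ct / sum over types.

    ``fits`` maps gene -> cell type -> fit (None/missing contributes 0).
    """
    for ct, n in cell_counts.items():
        if n < 0:
            raise ValidationError(f"negative cell count for {ct}")
    genes = list(fits)
    types = sorted(cell_counts)
    terms = np.zeros((len(genes), len(types)))
    for i, g in enumerate(genes):
        for j, ct in enumerate(types):
            fit = fits[g].get(ct)
            if fit is not None:
                terms[i, j] = expected_value(fit, expected_value_mode) * cell_counts[ct]
    totals = terms.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(totals[:, None] > 0, terms / np.maximum(totals[:, None], 1e-300), np.nan)
    terms_df = pd.DataFrame(terms, index=genes, columns=types)
    q_df = pd.DataFrame(q, index=genes, columns=types)
    undefined = q_df.index[totals == 0]
    return ContributionTable(cohort=cohort, q=q_df, terms=terms_df, undefined=undefined)


def call_specific_genes(
    tables: Mapping[str, ContributionTable],
    target_cell_type: str,
    tau: float = 0.8,
) -> pd.DataFrame:
    """Call genes whose target-type Q >= tau in every cohort.

    Returns a frame with one column of Q per cohort, the min-over-cohorts Q
    and the ``called`` flag, sorted by min Q descending.  Gene universes are
    intersected across cohorts when they differ (logged via warning).
    """
    if not tables:
        raise ConfigurationError("no contribution tables given")
    for cid, tab in tables.items():
        if target_cell_type not in tab.q.columns:
            raise ConfigurationError(
                f"target cell type {target_cell_type!r} absent from cohort {cid!r}"
            )
    cohort_ids = list(tables)
    universes = [set(tables[c].q.index) for c in cohort_ids]
    common = set.intersection(*universes)
    if any(len(u) != len(common) for u in universes):
        warnings.warn("gene universes differ across cohorts; using intersection", stacklevel=2)
    genes = sorted(common)
    qmat = pd.DataFrame(
        {c: tables[c].q.loc[genes, target_cell_type] for c in cohort_ids}, index=genes
    )
    out = qmat.copy()
    out.columns = [f"q_{c}" for c in cohort_ids]
    out["min_q"] = qmat.min(axis=1)
    out["called"] = (qmat >= tau).all(axis=1) & qmat.notna().all(axis=1)
    return out.sort_values("min_q", ascending=False)


def fit_cohort_contributions(
    expr: np.ndarray,
    obs: pd.DataFrame,
    gene_names: Sequence[str],
    cohort_key: str = "cohort",
    type_key: str = "cell_type",
    n_min_nonzero: int = DEFAULT_N_MIN_NONZERO,
    dropout_grid_step: float = 0.01,
    expected_value_mode: str = "plain",
    n_grid: int = 8,
) -> dict[str, ContributionTable]:
    """Fit hurdle models per gene x cell type within each cohort.

    Expression is rescaled to the unit interval per gene *per cohort* using
    the max over all of that cohort's cells, so every cell type of a gene
    shares one scale and the contribution ratio is scale-free.
    """
    expr = np.asarray(expr, dtype=float)
    tables: dict[str, ContributionTable] = {}
    for cohort in pd.unique(obs[cohort_key]):
        in_cohort = (obs[cohort_key] == cohort).to_numpy()
        xc = expr[in_cohort]
        types = pd.unique(obs.loc[in_cohort, type_key])
        scale = xc.max(axis=0) * (1.0 + RESCALE_EPS)
        type_masks = {
            ct: (obs.loc[in_cohort, type_key] == ct).to_numpy() for ct in types
        }
        cell_counts = {ct: int(m.sum()) for ct, m in type_masks.items()}
        fits: dict[str, dict[str, BetaHurdleFit | None]] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # low-support skips are expected in bulk fitting
            for j, g in enumerate(gene_names):
                fits[g] = {}
                if scale[j] <= 0:
                    continue
                col = xc[:, j] / scale[j]
                for ct, mask in type_masks.items():
                    fits[g][ct] = fit_hurdle(
                        col[mask],
                        dropout_grid_step=dropout_grid_step,
                        n_min_nonzero=n_min_nonzero,
                        n_grid=n_grid,
                    )
        tables[str(cohort)] = contribution_table(
            fits, cell_counts, cohort=str(cohort), expected_value_mode=expected_value_mode
        )
    return tables


@dataclass
class CullenFrey:
    """Squared skewness / kurtosis point with a bootstrap cloud."""

    skewness_sq: float
    kurtosis: float
    boot_skewness_sq: np.ndarray
    boot_kurtosis: np.ndarray

    @staticmethod
    def beta_region_bounds(skewness_sq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Kurtosis bounds of the beta family at given squared skewness.

        The beta family occupies the band between the all-distribution limit
        ``kurtosis = 1 + skew^2`` and the gamma line ``3 + 1.5 * skew^2``.
        """
        s2 = np.asarray(skewness_sq, dtype=float)
        return 1.0 + s2, 3.0 + 1.5 * s2


def cullen_frey_diagnostic(
    values: np.ndarray, n_boot: int = 200, seed: int = 0
) -> CullenFrey:
    """Locate a sample on the skewness²-kurtosis plane (Pearson, uncorrected)."""
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValidationError("need at least 10 values")
    if np.allclose(x, x[0]):
        raise ValidationError("constant input: moments undefined")

    def moments(v: np.ndarray) -> tuple[float, float]:
        c = v - v.mean()
        m2 = (c**2).mean()
        skew = (c**3).mean() / m2**1.5
        kurt = (c**4).mean() / m2**2
        return skew**2, kurt

    s2, k = moments(x)
    rng = np.random.default_rng(seed)
    boots = np.array(
        [moments(rng.choice(x, size=x.size, replace=True)) for _ in range(n_boot)]
    )
    return CullenFrey(s2, k, boots[:, 0], boots[:, 1])
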