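"""Synthetic islet scRNA-seq and bulk RNA-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-gene, per-cell-type expression follows a hurdle-beta law (a point
mass at zero plus a beta distribution on the open unit interval), cohorts vary
in beta-cell subtype composition, bulk samples are cell-count-weighted sums of
cell-type expected values with multiplicative noise and an optional exocrine
contamination share, and phenotypes can carry a planted linear dependence on a
module's latent co-expression signal.

Every generated dataset is accompanied by a :class:`SyntheticTruth` object
recording all parameters, so recovery by the analysis modules can be scored
against ground truth without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: beta variates are clipped away from {0, 1} so the support stays open
OPEN_UNIT_EPS = 1e-6

#: the six age x diet x sex cohorts of the study design
DEFAULT_COHORT_IDS = ("HF20", "HM20", "HF30", "HM30", "LF20", "LM20")

DEFAULT_CELL_TYPES = ("beta", "alpha", "delta", "acinar")
DEFAULT_EXOCRINE_TYPES = ("acinar",)
DEFAULT_SUBTYPES = ("Beta1", "Beta2", "Beta3", "Beta4")


@dataclass(frozen=True)
class BetaHurdleParams:
    """Hurdle-beta law for one gene in one cell type.

    ``pi0`` is the true-zero point mass; ``pr_dropout`` records what fraction
    of *observed* zeros the truth attributes to technical dropout.  Dropout
    zeros and true zeros are generated identically (both are observed 0); the
    attribution is unrecoverable from data and lives only in the truth object.
    """

    alpha: float
    beta_: float
    pi0: float = 0.0
    pr_dropout: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta_ > 0):
            raise ValidationError(
                f"beta shapes must be positive, got alpha={self.alpha}, beta={self.beta_}"
            )
        if not (0.0 <= self.pi0 <= 1.0 and 0.0 <= self.pr_dropout <= 1.0):
            raise ValidationError("pi0 and pr_dropout must lie in [0, 1]")

    @property
    def mean_nonzero(self) -> float:
        """Mean of the beta component, alpha / (alpha + beta)."""
        return self.alpha / (self.alpha + self.beta_)


@dataclass
class GeneSpec:
    """Per-cell-type hurdle-beta parameters for one gene.

    ``subtype_params`` optionally overrides the parent-cell-type law for cells
    carrying a given subtype label (used to plant subtype marker genes).
    """

    gene_id: str
    params: Mapping[str, BetaHurdleParams]
    subtype_params: Mapping[str, BetaHurdleParams] = field(default_factory=dict)

    def law_for(self, cell_type: str, subtype: str | None = None) -> BetaHurdleParams | None:
        if subtype is not None and subtype in self.subtype_params:
            return self.subtype_params[subtype]
        return self.params.get(cell_type)


@dataclass
class CohortSpec:
    """One age x diet x sex cohort: cell counts, subtype mix, bulk design."""

    cohort_id: str
    n_cells_per_type: Mapping[str, int]
    subtype_proportions: Mapping[str, float] = field(default_factory=dict)
    n_bulk_samples: int = 4
    trait_means: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ct, n in self.n_cells_per_type.items():
            if n < 0:
                raise ValidationError(f"negative cell count for {ct} in {self.cohort_id}")
        if self.subtype_proportions:
            total = float(sum(self.subtype_proportions.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"subtype proportions in {self.cohort_id} sum to {total}, expected 1"
                )


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the planted structure."""

    gene_specs: list[GeneSpec]
    cohorts: list[CohortSpec]
    specific_genes: set[str] = field(default_factory=set)
    module_assignments: dict[str, str] = field(default_factory=dict)
    module_trait_links: dict[str, tuple[str, float]] = field(default_factory=dict)
    subtype_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    exocrine_types: tuple[str, ...] = ()

    def to_json(self) -> str:
        def enc_spec(gs: GeneSpec) -> dict:
            return {
                "gene_id": gs.gene_id,
                "params": {ct: dataclasses.asdict(p) for ct, p in gs.params.items()},
                "subtype_params": {
                    st: dataclasses.asdict(p) for st, p in gs.subtype_params.items()
                },
            }

        payload = {
            "gene_specs": [enc_spec(g) for g in self.gene_specs],
            "cohorts": [
                {
                    "cohort_id": c.cohort_id,
                    "n_cells_per_type": dict(c.n_cells_per_type),
                    "subtype_proportions": dict(c.subtype_proportions),
                    "n_bulk_samples": c.n_bulk_samples,
                    "trait_means": dict(c.trait_means),
                }
                for c in self.cohorts
            ],
            "specific_genes": sorted(self.specific_genes),
            "module_assignments": self.module_assignments,
            "module_trait_links": {
                m: [t, e] for m, (t, e) in self.module_trait_links.items()
            },
            "subtype_proportions": self.subtype_proportions,
            "exocrine_types": list(self.exocrine_types),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        specs = [
            GeneSpec(
                gene_id=g["gene_id"],
                params={ct: BetaHurdleParams(**p) for ct, p in g["params"].items()},
                subtype_params={
                    st: BetaHurdleParams(**p) for st, p in g["subtype_params"].items()
                },
            )
            for g in raw["gene_specs"]
        ]
        cohorts = [CohortSpec(**c) for c in raw["cohorts"]]
        return cls(
            gene_specs=specs,
            cohorts=cohorts,
            specific_genes=set(raw["specific_genes"]),
            module_assignments=dict(raw["module_assignments"]),
            module_trait_links={
                m: (t, float(e)) for m, (t, e) in raw["module_trait_links"].items()
            },
            subtype_proportions=raw["subtype_proportions"],
            exocrine_types=tuple(raw["exocrine_types"]),
        )


def _draw_hurdle(rng: np.random.Generator, law: BetaHurdleParams, n: int) -> np.ndarray:
    values = rng.beta(law.alpha, law.beta_, size=n)
    np.clip(values, OPEN_UNIT_EPS, 1.0 - OPEN_UNIT_EPS, out=values)
    if law.pi0 > 0:
        values[rng.random(n) < law.pi0] = 0.0
    return values


def generate_cells(
    gene_specs: Sequence[GeneSpec],
    cohorts: Sequence[CohortSpec],
    seed: int,
    beta_cell_type: str = "beta",
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw a cell x gene expression matrix from the hurdle-beta laws.

    Cells are labelled with cell type, subtype (beta cells only; other cells
    carry their cell type as subtype) and cohort.  Identical seed gives
    byte-identical output.
    """
    if len(gene_specs) == 0:
        raise ConfigurationError("at least one gene spec is required")
    if len(cohorts) == 0:
        raise ConfigurationError("at least one cohort is required")
    cell_types = sorted({ct for gs in gene_specs for ct in gs.params})
    if not cell_types:
        raise ConfigurationError("gene specs define no cell types")

    rng = np.random.default_rng(seed)
    gene_ids = [gs.gene_id for gs in gene_specs]
    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []

    for cohort in cohorts:
        for ct in sorted(cohort.n_cells_per_type):
            n = int(cohort.n_cells_per_type[ct])
            if n == 0:
                continue
            if ct == beta_cell_type and cohort.subtype_proportions:
                subs = sorted(cohort.subtype_proportions)
                probs = np.array([cohort.subtype_proportions[s] for s in subs])
                subtype_of = rng.choice(len(subs), size=n, p=probs / probs.sum())
                subtypes = [subs[i] for i in subtype_of]
            else:
                subtypes = [ct] * n
            block = np.zeros((n, len(gene_specs)))
            sub_arr = np.asarray(subtypes)
            for j, gs in enumerate(gene_specs):
                base = gs.law_for(ct)
                overridden = [s for s in gs.subtype_params if s in set(subtypes)]
                if not overridden:
                    if base is not None:
                        block[:, j] = _draw_hurdle(rng, base, n)
                    continue
                # draw per subtype group so marker overrides apply
                for st in sorted(set(subtypes)):
                    mask = sub_arr == st
                    law = gs.law_for(ct, st)
                    if law is not None:
                        block[mask, j] = _draw_hurdle(rng, law, int(mask.sum()))
            blocks.append(block)
            for i in range(n):
                obs_rows.append(
                    {"cell_type": ct, "subtype": subtypes[i], "cohort": cohort.cohort_id}
                )

    matrix = np.vstack(blocks) if blocks else np.zeros((0, len(gene_specs)))
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell_{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(
        X=matrix, obs=obs, var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    )
    truth = SyntheticTruth(
        gene_specs=list(gene_specs),
        cohorts=list(cohorts),
        subtype_proportions={
            c.cohort_id: dict(c.subtype_proportions) for c in cohorts
        },
    )
    return adata, truth


def analytic_bulk(
    gene_specs: Sequence[GeneSpec],
    cohort: CohortSpec,
    exocrine_types: Sequence[str] = (),
    contamination_fraction: float = 0.0,
) -> pd.Series:
    """Analytic noise-free bulk values: sum over cell types of E[beta] * N.

    With ``contamination_fraction`` c > 0, exocrine terms are scaled so that
    summed over all genes they form fraction c of the library (the same
    scaling :func:`generate_bulk` applies); with c = 0 exocrine types
    contribute nothing and a cohort without exocrine types is unaffected.
    """
    kappa = _contamination_scale(gene_specs, cohort, exocrine_types, contamination_fraction)
    values = {}
    for gs in gene_specs:
        endo = exo = 0.0
        for ct, n in cohort.n_cells_per_type.items():
            law = gs.law_for(ct)
            if law is None:
                continue
            term = law.mean_nonzero * n
            if ct in exocrine_types:
                exo += term
            else:
                endo += term
        values[gs.gene_id] = endo + kappa * exo
    return pd.Series(values)


def _contamination_scale(
    gene_specs: Sequence[GeneSpec],
    cohort: CohortSpec,
    exocrine_types: Sequence[str],
    contamination_fraction: float,
) -> float:
    """Scale kappa applied to exocrine terms so they form the requested share."""
    t_endo = t_exo = 0.0
    for gs in gene_specs:
        for ct, n in cohort.n_cells_per_type.items():
            law = gs.law_for(ct)
            if law is None:
                continue
            term = law.mean_nonzero * n
            if ct in exocrine_types:
                t_exo += term
            else:
                t_endo += term
    if contamination_fraction == 0.0 or t_exo == 0.0:
        return 0.0
    c = contamination_fraction
    return c * t_endo / ((1.0 - c) * t_exo)


def generate_bulk(
    gene_specs: Sequence[GeneSpec],
    cohorts: Sequence[CohortSpec],
    noise_cv: float = 0.0,
    contamination_fraction: float = 0.0,
    exocrine_types: Sequence[str] = (),
    module_assignments: Mapping[str, str] | None = None,
    module_trait_links: Mapping[str, tuple[str, float]] | None = None,
    module_sd: float = 0.3,
    trait_sds: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Form bulk samples as cell-count-weighted sums of expected values.

    Each sample's value for gene g is ``sum_ct E[beta(alpha, beta)] * N_ct``,
    multiplied by mean-one lognormal noise with coefficient of variation
    ``noise_cv``.  Exocrine cell types contribute a ``contamination_fraction``
    share of the total library (flat ambient-style contamination).  Genes in a
    planted module share a per-sample latent signal z (log-scale loading
    ``module_sd``); a linked phenotype gets a linear dependence on the same z
    with the stated effect size, so module-trait correlation is planted.

    Returns ``(bulk, phenotypes)``: sample x gene values and sample x trait
    table (with ``cohort`` column).
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be non-negative")
    if not (0.0 <= contamination_fraction < 1.0):
        raise ValidationError("contamination_fraction must lie in [0, 1)")
    if contamination_fraction > 0 and not exocrine_types:
        raise ConfigurationError(
            "contamination requested but no exocrine cell type designated"
        )
    module_assignments = dict(module_assignments or {})
    module_trait_links = dict(module_trait_links or {})
    trait_sds = dict(trait_sds or {})
    rng = np.random.default_rng(seed)
    gene_ids = [gs.gene_id for gs in gene_specs]
    modules = sorted({m for m in module_assignments.values()})

    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    rows, pheno_rows, sample_ids = [], [], []
    for cohort in cohorts:
        kappa = _contamination_scale(
            gene_specs, cohort, exocrine_types, contamination_fraction
        )
        base = np.zeros(len(gene_specs))
        for j, gs in enumerate(gene_specs):
            endo = exo = 0.0
            for ct, n in cohort.n_cells_per_type.items():
                law = gs.law_for(ct)
                if law is None:
                    continue
                term = law.mean_nonzero * n
                if ct in exocrine_types:
                    exo += term
                else:
                    endo += term
            base[j] = endo + kappa * exo
        for s in range(cohort.n_bulk_samples):
            z = {m: rng.standard_normal() for m in modules}
            values = base.copy()
            if modules:
                loading = np.array(
                    [
                        math.exp(module_sd * z[module_assignments[g]])
                        if g in module_assignments
                        else 1.0
                        for g in gene_ids
                    ]
                )
                values = values * loading
            if sigma > 0:
                values = values * np.exp(rng.normal(-0.5 * sigma**2, sigma, len(values)))
            rows.append(values)
            sample_ids.append(f"{cohort.cohort_id}_s{s}")
            pheno = {"cohort": cohort.cohort_id}
            linked = {trait: (m, eff) for m, (trait, eff) in module_trait_links.items()}
            for trait, mean in cohort.trait_means.items():
                sd = float(trait_sds.get(trait, 1.0))
                if trait in linked:
                    m, eff = linked[trait]
                    noise = math.sqrt(max(0.0, 1.0 - eff**2))
                    pheno[trait] = mean + sd * (eff * z.get(m, 0.0) + noise * rng.standard_normal())
                else:
                    pheno[trait] = mean + sd * rng.standard_normal()
            pheno_rows.append(pheno)

    bulk = pd.DataFrame(rows, index=sample_ids, columns=gene_ids)
    phenotypes = pd.DataFrame(pheno_rows, index=sample_ids)
    return bulk, phenotypes


def simulate_coexpression(
    n_samples: int,
    module_sizes: Mapping[str, int],
    n_noise_genes: int,
    within_r: float = 0.8,
    trait_effects: Mapping[str, float] | None = None,
    trait_name: str = "trait",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Gaussian planted-module co-expression data for network-stage tests.

    Genes in module m are ``sqrt(r) * z_m + sqrt(1-r) * noise`` so every
    within-module gene pair has population correlation ``within_r``; noise
    genes are i.i.d. standard normal.  For each module with a trait effect e,
    the trait is ``e * z_m + sqrt(1-e^2) * noise`` (effects over multiple
    modules add on the z scale).

    Returns ``(expr, traits, labels)``: sample x gene expression, sample x 1
    trait table, and the true gene -> module labels ("noise" for noise genes).
    """
    if not (0.0 <= within_r < 1.0):
        raise ValidationError("within_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    trait_effects = dict(trait_effects or {})
    cols, labels, names = [], [], []
    z_by_module: dict[str, np.ndarray] = {}
    for m in sorted(module_sizes):
        z = rng.standard_normal(n_samples)
        z_by_module[m] = z
        size = int(module_sizes[m])
        loading = math.sqrt(within_r)
        resid = math.sqrt(1.0 - within_r)
        for _ in range(size):
            cols.append(loading * z + resid * rng.standard_normal(n_samples))
            labels.append(m)
    for _ in range(int(n_noise_genes)):
        cols.append(rng.standard_normal(n_samples))
        labels.append("noise")
    names = [f"G{i:04d}" for i in range(len(cols))]
    expr = pd.DataFrame(
        np.column_stack(cols) if cols else np.zeros((n_samples, 0)),
        index=[f"S{i:02d}" for i in range(n_samples)],
        columns=names,
    )
    trait = np.zeros(n_samples)
    total_eff = 0.0
    for m, eff in trait_effects.items():
        trait += eff * z_by_module[m]
        total_eff += eff**2
    trait += math.sqrt(max(0.0, 1.0 - total_eff)) * rng.standard_normal(n_samples)
    traits = pd.DataFrame({trait_name: trait}, index=expr.index)
    return expr, traits, pd.Series(labels, index=names, name="module")


@dataclass
class SyntheticDataset:
    """A bundled single-cell + bulk dataset with its ground truth."""

    adata: ad.AnnData
    bulk: pd.DataFrame | None = None
    phenotypes: pd.DataFrame | None = None
    truth: SyntheticTruth | None = None


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a dataset as a 10x-style MTX triplet plus TSV/JSON sidecars.

    Layout: ``matrix.mtx`` (genes x cells, 10x convention), ``features.tsv``,
    ``barcodes.tsv``, ``cells.tsv`` (per-cell metadata), ``bulk_counts.tsv``
    (genes x samples, samples as columns), ``phenotypes.tsv``, ``truth.json``
    and ``layout.json`` recording the matrix orientation.
    """
    from scipy import io as spio
    from scipy import sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adata = dataset.adata
    mat = sparse.csr_matrix(np.asarray(adata.X).T)  # genes x cells
    spio.mmwrite(str(out / "matrix.mtx"), mat)
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(out / "cells.tsv", sep="\t", index_label="barcode")
    (out / "layout.json").write_text(
        json.dumps({"matrix_orientation": "genes_x_cells", "format": "MatrixMarket"})
    )
    if dataset.bulk is not None:
        dataset.bulk.T.to_csv(out / "bulk_counts.tsv", sep="\t", index_label="gene")
    if dataset.phenotypes is not None:
        dataset.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index_label="sample")
    if dataset.truth is not None:
        (out / "truth.json").write_text(dataset.truth.to_json())
    return out


# ---------------------------------------------------------------------------
# Scenario builders: the study-design defaults used throughout the tests


def default_cell_counts(scale: float = 1.0) -> dict[str, int]:
    base = {"beta": 400, "alpha": 250, "delta": 150, "acinar": 200}
    return {ct: max(1, int(round(n * scale))) for ct, n in base.items()}


def default_subtype_proportions() -> dict[str, dict[str, float]]:
    """Cohort-varying Beta1-4 mixes: hyperglycemic-obese males are Beta1-heavy."""
    return {
        "HF20": {"Beta1": 0.35, "Beta2": 0.30, "Beta3": 0.25, "Beta4": 0.10},
        "HM20": {"Beta1": 0.50, "Beta2": 0.15, "Beta3": 0.25, "Beta4": 0.10},
        "HF30": {"Beta1": 0.30, "Beta2": 0.35, "Beta3": 0.25, "Beta4": 0.10},
        "HM30": {"Beta1": 0.25, "Beta2": 0.40, "Beta3": 0.25, "Beta4": 0.10},
        "LF20": {"Beta1": 0.25, "Beta2": 0.35, "Beta3": 0.30, "Beta4": 0.10},
        "LM20": {"Beta1": 0.25, "Beta2": 0.40, "Beta3": 0.25, "Beta4": 0.10},
    }


def default_trait_means() -> dict[str, dict[str, float]]:
    """Approximate cohort means for the six phenotypes (g, mg/dl, ng/ml, ratios)."""
    base = {
        "body_weight": 32.0,
        "blood_glucose": 150.0,
        "serum_insulin": 1.5,
        "gsis": 3.0,
        "basal_secretion": 0.15,
        "insulin_content": 10.0,
    }
    per_cohort = {}
    for cid in DEFAULT_COHORT_IDS:
        means = dict(base)
        if cid.startswith("H"):
            means["body_weight"] = 45.0
        if cid == "HM20":  # hyperglycemic-obese males
            means["blood_glucose"] = 280.0
            means["gsis"] = 1.5
            means["basal_secretion"] = 0.35
        pheno = dict(means)
        per_cohort[cid] = pheno
    return per_cohort


def default_cohorts(
    cell_scale: float = 1.0, n_bulk_samples: int = 4
) -> list[CohortSpec]:
    props = default_subtype_proportions()
    traits = default_trait_means()
    return [
        CohortSpec(
            cohort_id=cid,
            n_cells_per_type=default_cell_counts(cell_scale),
            subtype_proportions=props[cid],
            n_bulk_samples=n_bulk_samples,
            trait_means=traits[cid],
        )
        for cid in DEFAULT_COHORT_IDS
    ]


def beta_specific_scenario(
    n_genes: int = 50,
    n_specific: int = 10,
    cohorts: Sequence[CohortSpec] | None = None,
) -> tuple[list[GeneSpec], list[CohortSpec], set[str]]:
    """Gene specs with planted beta-cell-specific genes.

    Specific genes have >= 95% of expected expression (E[Y] * N, the
    attribution formula) from beta cells in every cohort; all other genes stay
    at <= 60%, leaving a clear margin around the 80% calling threshold.
    """
    if n_specific > n_genes:
        raise ConfigurationError("n_specific cannot exceed n_genes")
    cohorts = list(cohorts) if cohorts is not None else default_cohorts()
    cell_types = DEFAULT_CELL_TYPES
    specs: list[GeneSpec] = []
    specific_ids: set[str] = set()

    hi_beta = BetaHurdleParams(alpha=4.0, beta_=1.5, pi0=0.10)
    lo_other = BetaHurdleParams(alpha=0.12, beta_=10.0, pi0=0.40)
    for i in range(n_specific):
        gid = f"SPEC{i:03d}"
        specific_ids.add(gid)
        specs.append(GeneSpec(gid, {ct: (hi_beta if ct == "beta" else lo_other) for ct in cell_types}))

    shared = BetaHurdleParams(alpha=2.0, beta_=2.0, pi0=0.15)
    alpha_lean_a = BetaHurdleParams(alpha=3.0, beta_=1.0, pi0=0.10)
    alpha_lean_b = BetaHurdleParams(alpha=1.0, beta_=3.0, pi0=0.20)
    beta_lean_beta = BetaHurdleParams(alpha=1.5, beta_=1.5, pi0=0.10)
    beta_lean_other = BetaHurdleParams(alpha=1.0, beta_=3.0, pi0=0.20)
    profiles = [
        {ct: shared for ct in cell_types},
        {ct: (alpha_lean_a if ct == "alpha" else alpha_lean_b) for ct in cell_types},
        {ct: (beta_lean_beta if ct == "beta" else beta_lean_other) for ct in cell_types},
    ]
    for i in range(n_genes - n_specific):
        gid = f"BKG{i:03d}"
        specs.append(GeneSpec(gid, dict(profiles[i % len(profiles)])))
    return specs, cohorts, specific_ids


def subtype_marker_scenario(
    n_markers_per_subtype: int = 5,
    n_background: int = 30,
    subtypes: Sequence[str] = DEFAULT_SUBTYPES,
) -> tuple[list[GeneSpec], set[str], dict[str, set[str]]]:
    """Gene specs planting private marker genes for each beta subtype."""
    base = BetaHurdleParams(alpha=1.5, beta_=4.0, pi0=0.2)
    high = BetaHurdleParams(alpha=6.0, beta_=1.5, pi0=0.02)
    other = BetaHurdleParams(alpha=0.3, beta_=6.0, pi0=0.5)
    specs: list[GeneSpec] = []
    markers: dict[str, set[str]] = {st: set() for st in subtypes}
    for st in subtypes:
        for i in range(n_markers_per_subtype):
            gid = f"MK_{st}_{i}"
            markers[st].add(gid)
            specs.append(
                GeneSpec(gid, {"beta": base}, subtype_params={st: high, **{s: other for s in subtypes if s != st}})
            )
    for i in range(n_background):
        specs.append(GeneSpec(f"NULL{i:03d}", {"beta": base}))
    all_marker_ids = {g for s in markers.values() for g in s}
    return specs, all_marker_ids, markers
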