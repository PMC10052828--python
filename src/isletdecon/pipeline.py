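"""Pipeline orchestrator: QC -> attribution -> markers -> composition ->
overlap -> phenotypes -> network, with a reproducible run manifest.

Each stage persists its outputs as TSV/JSON under the run directory; a failed
stage halts with a stage-named error and earlier outputs are preserved.  The
configuration is a flat dataclass loadable from YAML with unknown keys
rejected, so a manifest plus config suffices to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import composition as comp
from . import hurdle, io, markers, network, qc
from .errors import ConfigurationError, IsletDeconError
from .permutation import overlap_permutation_test


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "run"
    seed: int = 0
    # stage toggles
    run_qc: bool = True
    run_specific: bool = True
    run_markers: bool = True
    run_composition: bool = True
    run_overlap: bool = True
    run_network: bool = True
    # qc
    n_feature_range: tuple[int, int] = (500, 3000)
    n_count_range: tuple[int, int] = (1000, 30000)
    pct_mito_range: tuple[float, float] = (0.0, 30.0)
    residual_sd_k: float = 3.0
    mito_prefix: str = "mt-"
    scale_factor: float = 1e4
    # hurdle
    target_cell_type: str = "beta"
    tau: float = 0.8
    dropout_grid_step: float = 0.01
    n_min_nonzero: int = 20
    expected_value_mode: str = "plain"
    # markers
    subtype_lfc_min: float = 0.1
    subtype_alpha: float = 0.01
    # composition
    n_sample: int = 1000
    n_boot: int = 100
    # permutation
    n_perm: int = 1000
    # network
    power: float = 8.0
    min_module_size: int = 5
    cut_height: float = 0.995
    kdiff_cohort_a: str = "HM20"
    kdiff_cohort_b: str = "HM30"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_feature_range", "n_count_range", "pct_mito_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(IsletDeconError):
    """A pipeline stage failed; the stage name prefixes the message."""


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    in_dir = Path(config.input_dir)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": [],
    }

    def run_stage(name: str, enabled: bool, fn) -> None:
        if not enabled:
            manifest["stages"].append({"name": name, "status": "skipped"})
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - halt with stage-named error
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "status": "ok"})

    adata = io.read_expression(in_dir)
    state: dict = {"adata": adata}

    def stage_qc() -> None:
        a = state["adata"]
        counts = np.asarray(a.X)
        thresholds = qc.QCThresholds(
            n_feature_range=config.n_feature_range,
            n_count_range=config.n_count_range,
            pct_mito_range=config.pct_mito_range,
            residual_sd_k=config.residual_sd_k,
        )
        keep, table = qc.qc_pipeline(counts, a.var_names, thresholds, config.mito_prefix)
        table.index = a.obs_names
        io.write_table(table, out / "qc_report.tsv", index_label="barcode")
        state["adata"] = a[keep].copy()

    def stage_specific() -> None:
        a = state["adata"]
        norm = qc.log_normalize(np.asarray(a.X), config.scale_factor)
        state["norm"] = norm
        tables = hurdle.fit_cohort_contributions(
            norm,
            a.obs,
            list(a.var_names),
            n_min_nonzero=config.n_min_nonzero,
            dropout_grid_step=config.dropout_grid_step,
            expected_value_mode=config.expected_value_mode,
        )
        calls = hurdle.call_specific_genes(tables, config.target_cell_type, config.tau)
        io.write_table(calls, out / "specific_genes.tsv", index_label="gene")
        state["specific"] = calls

    def stage_markers() -> None:
        a = state["adata"]
        norm = state.get("norm")
        if norm is None:
            norm = qc.log_normalize(np.asarray(a.X), config.scale_factor)
        is_target = (a.obs["cell_type"] == config.target_cell_type).to_numpy()
        sub = norm[is_target]
        labels = a.obs.loc[is_target, "subtype"]
        profiles = markers.subtype_profiles(
            sub,
            labels,
            gene_names=list(a.var_names),
            lfc_min=config.subtype_lfc_min,
            alpha=config.subtype_alpha,
        )
        for st, tab in profiles.items():
            io.write_table(tab, out / f"markers_{st}.tsv", index_label="gene")
        state["profiles"] = profiles

    def stage_composition() -> None:
        a = state["adata"]
        obs = a.obs[a.obs["cell_type"] == config.target_cell_type]
        estimates = comp.compositions_by_cohort(
            obs, n_sample=config.n_sample, n_boot=config.n_boot, seed=config.seed
        )
        io.write_table(
            comp.composition_long_table(estimates), out / "composition.tsv"
        )
        io.write_table(
            comp.compare_compositions(estimates), out / "composition_comparisons.tsv"
        )

    def stage_overlap() -> None:
        calls = state.get("specific")
        profiles = state.get("profiles")
        if calls is None or not profiles:
            raise ConfigurationError("overlap stage needs specific-gene and marker outputs")
        universe = list(state["adata"].var_names)
        specific = set(calls.index[calls.called])
        first = sorted(profiles)[0]
        over = set(profiles[first].index[profiles[first].significant])
        test = overlap_permutation_test(
            specific, over, universe, n_perm=config.n_perm, seed=config.seed
        )
        (out / "overlap.json").write_text(
            json.dumps(
                {
                    "subtype": first,
                    "universe_size": test.universe_size,
                    "set_a_size": test.set_a_size,
                    "set_b_size": test.set_b_size,
                    "observed_overlap": test.observed_overlap,
                    "p_value": test.p_value,
                    "n_perm": test.n_perm,
                },
                indent=1,
            )
        )

    def stage_network() -> None:
        bulk_path = in_dir / "bulk_counts.tsv"
        pheno_path = in_dir / "phenotypes.tsv"
        if not bulk_path.exists():
            raise ConfigurationError("network stage needs bulk_counts.tsv in the input dir")
        bulk = io.read_bulk_counts(bulk_path)
        calls = state.get("specific")
        if calls is not None:
            genes = [g for g in calls.index[calls.called] if g in bulk.columns]
            if len(genes) >= max(10, 2 * config.min_module_size):
                bulk = bulk[genes]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = network.normalize_bulk(bulk)
            net = network.build_network(
                norm,
                power=config.power,
                min_module_size=config.min_module_size,
                cut_height=config.cut_height,
            )
        io.write_table(net.module_labels.to_frame(), out / "modules.tsv", index_label="gene")
        io.write_table(net.eigengenes, out / "eigengenes.tsv", index_label="sample")
        io.write_table(net.k_within.to_frame(), out / "k_within.tsv", index_label="gene")
        io.write_table(
            network.edge_list(net.adjacency, min_weight=0.01), out / "edges.tsv"
        )
        if pheno_path.exists():
            pheno = io.read_phenotypes(pheno_path)
            traits = pheno.select_dtypes(include=[np.number])
            if net.eigengenes.shape[1] and traits.shape[1]:
                mt = network.module_trait(net.eigengenes, traits.loc[net.eigengenes.index])
                io.write_table(mt, out / "module_trait.tsv")
                scores = network.inverse_normal_transform(norm)
                io.write_table(
                    network.module_membership(scores, net.eigengenes),
                    out / "kme.tsv",
                    index_label="gene",
                )
            cohorts = pheno.get("cohort")
            if cohorts is not None:
                a_mask = (cohorts == config.kdiff_cohort_a).to_numpy()
                b_mask = (cohorts == config.kdiff_cohort_b).to_numpy()
                if a_mask.sum() >= 4 and b_mask.sum() >= 4:
                    scores = network.inverse_normal_transform(norm)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        dc = network.differential_connectivity(
                            scores.loc[a_mask], scores.loc[b_mask],
                            net.module_labels, power=config.power,
                        )
                    io.write_table(dc, out / "kdiff.tsv", index_label="gene")

    run_stage("qc", config.run_qc, stage_qc)
    run_stage("specific", config.run_specific, stage_specific)
    run_stage("markers", config.run_markers, stage_markers)
    run_stage("composition", config.run_composition, stage_composition)
    run_stage("overlap", config.run_overlap and config.run_specific and config.run_markers, stage_overlap)
    run_stage("network", config.run_network, stage_network)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
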