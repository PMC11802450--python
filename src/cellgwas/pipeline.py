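"""Orchestration: tie the stages into the end-to-end analysis.

Two entry points: :func:`run_synthetic` runs everything in memory from a
:class:`~cellgwas.simulate.SimulationConfig` (what the tests, the power
harness and the acceptance checks use), and :func:`run_pipeline` runs the
file-based pipeline described by a :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as cgio
from .simulate import SimulationConfig, simulate_all, config_to_dict
from .specificity import (
    cluster_means,
    compute_specificity,
    downsample_clusters,
    filter_genes,
    DEFAULT_MHC,
)
from .gene_assoc import (
    run_gene_analysis,
    DEFAULT_WINDOW_UP,
    DEFAULT_WINDOW_DOWN,
)
from .regression import ScanEngine
from .conditional import forward_stepwise

log = logging.getLogger("cellgwas")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """File paths and tunables for the file-based pipeline."""

    gwas_path: str = ""
    annotation_path: str = ""
    panel_prefix: str = ""
    counts_prefix: str = ""
    out_dir: str = "results"
    window_up: int = DEFAULT_WINDOW_UP
    window_down: int = DEFAULT_WINDOW_DOWN
    mhc: tuple = DEFAULT_MHC
    alpha: float = 0.05
    rule2_use_conditional: bool = True
    downsample_max_cells: tuple = (3_400, 340, 34)
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["mhc"] = list(d["mhc"])
        d["downsample_max_cells"] = list(d["downsample_max_cells"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "mhc" in d:
            d["mhc"] = tuple(d["mhc"])
        if "downsample_max_cells" in d:
            d["downsample_max_cells"] = tuple(d["downsample_max_cells"])
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise StageError(name, exc) from exc
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def run_synthetic(
    config: SimulationConfig,
    alpha: float = 0.05,
    max_cells: int | None = None,
    run_selection: bool = True,
    truth=None,
) -> dict:
    """Full in-memory pipeline on one synthetic dataset.

    Returns a dict with the simulated inputs plus: ``specificity``,
    ``gene_stats``, ``corr``, ``scan`` (per-cell-type associations) and
    ``selection`` (forward-stepwise result; None if not requested).
    """
    sim = simulate_all(config, truth=truth)
    counts, labels = sim["counts"], sim["labels"]
    if max_cells is not None:
        counts, labels = downsample_clusters(counts, labels, max_cells, seed=config.seed)
    expr = cluster_means(counts, labels, gene_ids=list(sim["genes"]["gene"]))
    expr, report = filter_genes(expr, sim["genes"])
    spec = compute_specificity(expr)
    gene_stats, corr, models = run_gene_analysis(
        sim["gwas"], sim["genes"], sim["panel"], sim["snps"]
    )
    engine = ScanEngine(gene_stats, spec, corr)
    scan = engine.scan(alpha=alpha)
    selection = forward_stepwise(scan, engine=engine) if run_selection else None
    sim.update(
        {
            "specificity": spec,
            "filter_report": report,
            "gene_stats": gene_stats,
            "corr": corr,
            "models": models,
            "engine": engine,
            "scan": scan,
            "selection": selection,
            "cells_per_cluster": expr.cells_per_cluster,
        }
    )
    return sim


@_stage("simulate")
def stage_simulate(config: SimulationConfig, out_dir) -> None:
    """Write a full synthetic input bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_all(config)
    cgio.write_gwas(sim["gwas"], out / "gwas.tsv")
    cgio.write_gene_annotation(sim["genes"], out / "genes.tsv")
    cgio.write_panel(sim["panel"], sim["snps"], out / "panel")
    cgio.write_counts(sim["counts"], sim["labels"], list(sim["genes"]["gene"]), out / "counts")
    sim["truth"].to_json(out / "truth.json")
    (out / "sim_config.json").write_text(json.dumps(config_to_dict(config), indent=1))


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline: read inputs, run all stages, write all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "pipeline_config.yaml")  # provenance

    @_stage("specificity")
    def _specificity():
        counts, labels, gene_ids = cgio.read_counts(config.counts_prefix)
        annotation = cgio.read_gene_annotation(config.annotation_path)
        expr = cluster_means(counts, labels, gene_ids=gene_ids)
        expr, report = filter_genes(expr, annotation, mhc=config.mhc)
        spec = compute_specificity(expr)
        cgio.write_specificity(spec, out / "specificity.tsv")
        cgio.write_filter_report(report, out / "gene_filter_report.json")
        return spec, expr.cells_per_cluster

    @_stage("gene_assoc")
    def _gene_assoc():
        gwas = cgio.read_gwas(config.gwas_path)
        annotation = cgio.read_gene_annotation(config.annotation_path)
        panel, snps = cgio.read_panel(config.panel_prefix)
        gene_stats, corr, _ = run_gene_analysis(
            gwas, annotation, panel, snps, config.window_up, config.window_down
        )
        cgio.write_gene_stats(gene_stats, out / "gene_stats.tsv")
        cgio.write_gene_correlation(corr, out / "gene_correlation.tsv")
        return gene_stats, corr

    @_stage("celltype_regression")
    def _scan(gene_stats, spec, corr):
        engine = ScanEngine(gene_stats, spec, corr)
        scan = engine.scan(alpha=config.alpha)
        scan.to_csv(out / "celltype_scan.tsv", sep="\t", index=False)
        return engine, scan

    @_stage("conditional_selection")
    def _select(engine, scan):
        selection = forward_stepwise(
            scan, engine=engine, rule2_use_conditional=config.rule2_use_conditional
        )
        sel_df = pd.DataFrame(
            {
                "CELLTYPE": list(selection.status),
                "STATUS": list(selection.status.values()),
            }
        ).merge(scan[["CELLTYPE", "P_ONESIDED"]], on="CELLTYPE")
        sel_df = sel_df.rename(columns={"P_ONESIDED": "MARGINAL_P"})
        sel_df.to_csv(out / "selection.tsv", sep="\t", index=False)
        selection.audit.to_csv(out / "conditional_audit.tsv", sep="\t", index=False)
        return selection

    spec, cells_per_cluster = _specificity()
    gene_stats, corr = _gene_assoc()
    engine, scan = _scan(gene_stats, spec, corr)
    selection = _select(engine, scan)
    return {
        "specificity": spec,
        "cells_per_cluster": cells_per_cluster,
        "gene_stats": gene_stats,
        "corr": corr,
        "scan": scan,
        "selection": selection,
        "out_dir": out,
    }
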