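"""End-to-end orchestration: simulate/load -> assign -> call -> CN -> variance -> response.

The pipeline runs each analysis stage in order, writes every stage's tables
to the output directory, and finishes with a JSON run report (package
version, seed, thresholds, row counts per stage). Rerunning with the same
configuration and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .copy_number import compare_group_depths, coverage_table
from .guides import (
    assign_guides,
    assignments_to_frame,
    count_guides_per_cell,
    filter_guide_reads,
    summarize_assignment,
)
from .heteroplasmy import combined_heteroplasmy, filter_by_combined_depth, infer_orientations
from .response import (
    compare_pc1_groups,
    pc_scores,
    phase_composition_test,
    residualize_expression,
    select_top_variable,
)
from .synthetic import generate_cohort, generate_expression, generate_guide_reads
from .tables import write_panel, write_table
from .variance import bh_adjust, holm_adjust, simulate_bottleneck_null

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("assign", "heteroplasmy", "copy_number", "variance", "response")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Thresholds, simulation parameters and paths for one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    n_cells: int = 3000
    # guide assignment
    mapq_min: int = 30
    min_reads: int = 2
    dominance: float = 2.0 / 3.0
    dedup_by_umi: bool = False
    reads_per_cell_mean: float = 5.0
    ambient_rate: float = 0.1
    # heteroplasmy
    min_depth: int = 20
    infer_orientation: bool = True
    # variance
    n_sims: int = 1000
    reference_gene: str = "NT"
    # response
    n_genes: int = 300
    top_k: int = 100
    log10_covariate: bool = False

    def validate(self) -> None:
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")
        if not 0.0 < self.dominance < 1.0:
            raise ValueError("dominance must lie in (0, 1)")
        if self.min_depth < 0 or self.min_reads < 0:
            raise ValueError("thresholds must be non-negative")
        if self.n_sims < 1 or self.n_cells < 10:
            raise ValueError("n_sims >= 1 and n_cells >= 10 required")

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic cohort and write a report bundle.

    Returns the run report (also written to ``<outdir>/run_report.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "mapq_min": config.mapq_min,
            "min_reads": config.min_reads,
            "dominance": config.dominance,
            "min_depth": config.min_depth,
        },
        "stages": {},
    }

    stage = "simulate"
    try:
        cohort = generate_cohort(config.n_cells, seed=config.seed)
        reads = generate_guide_reads(
            cohort.metadata,
            reads_per_cell_mean=config.reads_per_cell_mean,
            ambient_rate=config.ambient_rate,
            seed=config.seed + 1,
        )
        expr = generate_expression(
            cohort.truth, cohort.coverage, n_genes=config.n_genes, seed=config.seed + 2
        )
        write_table(cohort.allele_counts, outdir / "allele_counts.tsv")
        write_table(cohort.coverage, outdir / "coverage.tsv")
        write_table(cohort.metadata, outdir / "metadata.tsv")
        write_panel(cohort.panel, outdir / "panel.tsv")
        report["stages"][stage] = {"n_cells": int(config.n_cells), "n_guide_reads": len(reads)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "assign"
    try:
        kept = filter_guide_reads(reads, config.mapq_min)
        counts = count_guides_per_cell(kept, dedup_by_umi=config.dedup_by_umi)
        assignments = assign_guides(
            counts,
            min_reads=config.min_reads,
            dominance=config.dominance,
            all_cells=cohort.metadata["cell_barcode"].tolist(),
        )
        adf = assignments_to_frame(assignments)
        write_table(adf, outdir / "assignments.tsv")
        summary = summarize_assignment(assignments, n_cells_total=config.n_cells)
        _write_json(summary, outdir / "assignment_summary.json")
        report["stages"][stage] = {
            "n_rows": len(adf),
            "assigned": summary["statuses"]["assigned"]["count"],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "heteroplasmy"
    try:
        panel = cohort.panel
        if config.infer_orientation:
            panel = infer_orientations(cohort.allele_counts, panel)
        calls = combined_heteroplasmy(cohort.allele_counts, panel)
        calls_deep = filter_by_combined_depth(calls, config.min_depth)
        write_table(calls, outdir / "calls.tsv")
        write_table(calls_deep, outdir / "calls_filtered.tsv")
        report["stages"][stage] = {"n_calls": len(calls), "n_pass_depth": len(calls_deep)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # analysis below restricts to confidently assigned cells of the true guide's gene
    meta = cohort.metadata.merge(
        adf[adf["status"] == "assigned"][["cell_barcode"]], on="cell_barcode"
    )

    stage = "copy_number"
    try:
        cov = coverage_table(cohort.coverage, genome_length=cohort.panel.genome_length)
        cov = cov.merge(meta[["cell_barcode", "target_gene"]], on="cell_barcode")
        cn_table = compare_group_depths(cov, group_col="target_gene", log10_transform=True)
        write_table(cn_table, outdir / "copy_number_comparisons.tsv")
        report["stages"][stage] = {"n_pairs": len(cn_table)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "variance"
    try:
        calls_meta = calls.merge(meta[["cell_barcode", "target_gene"]], on="cell_barcode")
        control = calls_meta[calls_meta["target_gene"] == config.reference_gene]
        rows = []
        kd_genes = [
            g for g in sorted(calls_meta["target_gene"].unique())
            if g != config.reference_gene
        ]
        for i, gene in enumerate(kd_genes):
            kd = calls_meta[calls_meta["target_gene"] == gene]
            if len(kd) < 2 or len(control) < len(kd):
                continue
            null = simulate_bottleneck_null(
                control["heteroplasmy"].to_numpy(),
                kd["combined_depth"].to_numpy(),
                n_kd=len(kd),
                observed_variance=float(kd["heteroplasmy"].var(ddof=1)),
                n_sims=config.n_sims,
                seed=config.seed + 100 + i,
            )
            rows.append(
                {
                    "target_gene": gene,
                    "n_cells": len(kd),
                    "observed_variance": null.observed_variance,
                    "null_mean_variance": float(null.null_variances.mean()),
                    "p_empirical": null.p_empirical,
                }
            )
        var_table = pd.DataFrame(rows)
        if len(var_table):
            var_table["p_adjusted"] = holm_adjust(var_table["p_empirical"].to_numpy())
        write_table(var_table, outdir / "variance_null.tsv")
        report["stages"][stage] = {"n_groups_tested": len(var_table)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "response"
    try:
        expr_meta = expr.loc[expr.index.intersection(meta["cell_barcode"])]
        cov_idx = cohort.coverage.set_index("cell_barcode")
        covariate = cov_idx.loc[expr_meta.index, "mean_coverage"].to_numpy()
        if config.log10_covariate:
            covariate = np.log10(np.where(covariate > 0, covariate, np.nan))
        model = residualize_expression(expr_meta, covariate)
        top = select_top_variable(model.residuals, k=config.top_k)
        pcs = pc_scores(model.residuals[top], n_components=2)
        meta_idx = meta.set_index("cell_barcode").loc[expr_meta.index]
        pc1 = pcs.scores["PC1"]
        pc1_table = compare_pc1_groups(pc1, meta_idx["target_gene"], config.reference_gene)
        phase_table = phase_composition_test(meta_idx["phase"], meta_idx["target_gene"])
        scores_out = pcs.scores.reset_index(names="cell_barcode")
        write_table(scores_out, outdir / "pc_scores.tsv")
        write_table(pc1_table, outdir / "pc1_group_tests.tsv")
        write_table(phase_table, outdir / "phase_composition.tsv")
        report["stages"][stage] = {
            "n_cells": len(expr_meta),
            "n_top_genes": len(top),
            "pc1_explained_variance": float(pcs.explained_variance[0]),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report["n_stages_completed"] = len(report["stages"])
    _write_json(report, outdir / "run_report.json")
    return report
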