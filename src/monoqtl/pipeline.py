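"""End-to-end pipeline: QC -> eQTL scan -> sharing -> co-expression.

Stages communicate through files in the output directory so that any
stage's result can be inspected and the expensive scan need not be
re-run to tweak a downstream step.  A machine-readable manifest records
the configuration, its hash, per-stage record counts and reconciliation
(cells in = excluded + analyzed; tests attempted = usable + skipped).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

import monoqtl
from monoqtl.coexpression import analyze_coexpression, module_partition
from monoqtl.datamodel import (
    CTMatrix,
    read_ct_matrix,
    read_genotypes,
    write_ct_matrix,
)
from monoqtl.eqtl import METHODS, run_eqtl_scan, significant_hits
from monoqtl.qc import apply_qc, ct_to_expression, detect_on_off_genes, exclude_nonsinglets
from monoqtl.sharing import sharing_analysis


@dataclass
class RunConfig:
    ct_matrix: str
    genotypes: str
    output_dir: str
    ct_meta: str | None = None
    lod: float = 28.0
    total_cycles: float = 40.0
    failure_sd: float = 2.0
    methods: Sequence[str] = METHODS
    fdr_q: float = 0.1
    tweedie_power: float | None = None
    loading_threshold: float = 0.7
    pc_selection: str = "pc1"
    make_figures: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.total_cycles > self.lod > 0:
            raise ValueError("need total_cycles > lod > 0")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        unknown = set(self.methods) - set(METHODS) - {"naive_mw"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write artifacts; returns the manifest dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": monoqtl.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    # --- stage: load + QC
    ct = read_ct_matrix(config.ct_matrix, meta_path=config.ct_meta)
    n_in = ct.n_cells
    ct = exclude_nonsinglets(ct)
    n_singlet = ct.n_cells
    ct_clean, qc_report = apply_qc(
        ct, k_sd=config.failure_sd, total_cycles=config.total_cycles
    )
    qc_report.cell_table.to_csv(out / "qc_cells.tsv", sep="\t")
    with open(out / "qc_report.json", "w") as fh:
        payload = qc_report.to_json_dict()
        payload["n_nonsinglet"] = n_in - n_singlet
        json.dump(payload, fh, indent=2)
    expr = ct_to_expression(ct_clean, config.total_cycles, config.lod)
    manifest["stages"]["qc"] = {
        "cells_in": n_in,
        "cells_nonsinglet": n_in - n_singlet,
        "cells_failure_excluded": int(qc_report.cell_table["excluded"].sum()),
        "cells_analyzed": expr.values.shape[0],
    }
    assert (
        manifest["stages"]["qc"]["cells_in"]
        == manifest["stages"]["qc"]["cells_nonsinglet"]
        + manifest["stages"]["qc"]["cells_failure_excluded"]
        + manifest["stages"]["qc"]["cells_analyzed"]
    )

    genotypes = read_genotypes(config.genotypes)

    # --- stage: eQTL scan
    table = run_eqtl_scan(
        expr, genotypes, methods=config.methods, fdr_q=config.fdr_q,
        tweedie_power=config.tweedie_power,
    )
    table.to_csv(out / "eqtl_full.tsv", sep="\t", index=False)
    hits = significant_hits(table)
    hits_out = hits.rename(columns={"rsid": "snp_rsid", "gene": "associated_transcript"})
    hits_out[["snp_rsid", "associated_transcript", "method", "cell_type",
              "effect", "p_value", "fdr_q", "direction"]].to_csv(
        out / "eqtl_significant.tsv", sep="\t", index=False)
    usable = int((table["converged"] & table["p_value"].notna()).sum())
    manifest["stages"]["scan"] = {
        "tests_attempted": len(table),
        "tests_usable": usable,
        "tests_skipped": int(len(table) - usable),
        "n_significant_records": len(hits),
    }

    # --- stage: sharing
    summary = sharing_analysis(hits) if not hits.empty else None
    if summary is not None:
        summary.to_json(out / "sharing.json")
        manifest["stages"]["sharing"] = {
            "n_shared": summary.n_shared,
            "n_cl_exclusive": summary.n_cl_exclusive,
            "n_ncl_exclusive": summary.n_ncl_exclusive,
        }
    else:
        (out / "sharing.json").write_text(json.dumps({"n_records": 0}))
        manifest["stages"]["sharing"] = {"n_shared": 0, "n_cl_exclusive": 0,
                                         "n_ncl_exclusive": 0}

    # --- stage: on/off pattern
    try:
        onoff = detect_on_off_genes(expr)
        onoff.drop(columns="status").to_csv(out / "on_off_genes.tsv", sep="\t")
        manifest["stages"]["on_off"] = {"n_flagged": int(onoff["flagged"].sum())}
    except ValueError as exc:
        manifest["stages"]["on_off"] = {"skipped": str(exc)}

    # --- stage: co-expression
    coexpr_modules = {}
    for cell_type in sorted(expr.cell_meta["cell_type"].unique()):
        try:
            res = analyze_coexpression(
                expr, cell_type, threshold=config.loading_threshold,
                pc_selection=config.pc_selection,
            )
        except ValueError as exc:
            manifest["stages"][f"coexpression_{cell_type}"] = {"skipped": str(exc)}
            continue
        res.mean_correlation.to_csv(out / f"mean_correlation_{cell_type}.tsv", sep="\t")
        eigen = pd.DataFrame({
            "eigenvalue": res.eigenvalues,
            "variance_explained": res.variance_explained,
        })
        eigen.to_csv(out / f"eigen_{cell_type}.tsv", sep="\t", index_label="component")
        res.cell_scores.to_csv(out / f"cell_scores_{cell_type}.tsv", sep="\t")
        coexpr_modules[cell_type] = res.modules.get("PC1", [])
        manifest["stages"][f"coexpression_{cell_type}"] = {
            "n_genes_universe": len(res.gene_universe),
            "pc1_variance_explained": float(res.variance_explained[0]),
            "module_size_pc1": len(coexpr_modules[cell_type]),
        }
        if config.make_figures:
            from monoqtl.plots import pc_scatter

            pc_scatter(res.cell_scores, f"{cell_type} cells, averaged-correlation PCA",
                       out / f"pca_{cell_type}.png")
    if {"CL", "NCL"} <= set(coexpr_modules):
        partition = module_partition(coexpr_modules["CL"], coexpr_modules["NCL"])
        pd.DataFrame.from_dict(partition, orient="index").T.to_csv(
            out / "modules_partition.tsv", sep="\t", index=False)
    with open(out / "modules.json", "w") as fh:
        json.dump(coexpr_modules, fh, indent=2)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def simulate_to_files(config, seed: int, out_dir: str | Path) -> dict:
    """Write a simulated dataset (CT CSV, genotype TSV, truth JSON) to disk."""
    from monoqtl.datamodel import write_genotypes
    from monoqtl.simulate import simulate_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct, truth = simulate_expression(config, seed)
    write_ct_matrix(ct, out / "ct_matrix.csv")
    write_genotypes(truth.genotypes, out / "genotypes.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2)
    return {"ct_matrix": str(out / "ct_matrix.csv"),
            "genotypes": str(out / "genotypes.tsv"),
            "truth": str(out / "truth.json")}
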