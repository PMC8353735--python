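"""End-to-end orchestration: simulate/ingest -> QC -> LTMG DE -> modules ->
enrichment -> flux -> proteomics, with a machine-readable run report.

Every stage writes plain files into the output directory so any stage can
be re-run in isolation; the report echoes the configuration and the
per-stage counts (cells retained, DEGs up/down at the FDR cutoff, module
count, enrichment hits, flux comparison summary).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .containers import ConfigError, DataError, ExpressionMatrix, read_expression_matrix
from . import enrichment as enr
from . import flux as flx
from . import ltmg, mebf, proteomics, qc, synthetic


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    outdir: str
    seed: int = 0
    # input: either a counts directory (counts.mtx + sidecars) or synthetic
    counts_dir: str | None = None
    synthetic: dict = {}
    # qc
    min_genes: int = 250
    max_genes: int = 10000
    max_mito: float = 0.15
    min_cells_gene: int = 2
    # ltmg / deg
    kmax: int = 3
    fdr_alpha: float = 0.05
    deg_groups: tuple[str, str] = ("siRef1_hypoxia", "Scr_hypoxia")
    # mebf
    rank_budget: int = 10
    mebf_t: float = 0.8
    # enrichment
    enrich_alpha: float = 0.001
    pathways_gmt: str | None = None
    tf_gmt: str | None = None
    # flux
    flux_lambda: float = 1.0
    flux_groups: tuple[str, str] = ("Scr_hypoxia", "siRef1_hypoxia")
    graph_json: str | None = None
    # proteomics
    dep_alpha: float = 0.01
    proteins_dir: str | None = None
    dep_groups: tuple[str, str] = ("siRef1_hypoxia", "Scr_hypoxia")


def ingest_external_counts(counts_path, cells_path, genes_path=None) -> ExpressionMatrix:
    """Load user-supplied counts (MTX + sidecars or dense TSV).

    Mitochondrial genes are flagged by the ``MT-`` symbol prefix unless the
    genes sidecar provides an ``is_mito`` column.
    """
    return read_expression_matrix(counts_path, cells_path, genes_path)


def run_pipeline(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.model_dump()}

    # ---- stage: input -----------------------------------------------------
    truth = None
    if config.counts_dir:
        d = Path(config.counts_dir)
        if not d.exists():
            raise DataError(f"stage input: counts directory {d} not found")
        em = ExpressionMatrix.read(d)
    else:
        scfg = synthetic.SyntheticConfig(**{"seed": config.seed, **config.synthetic})
        em, truth = synthetic.generate_counts(scfg)
        em.write(outdir / "simulated")
        truth.to_json(outdir / "simulated" / "truth.json")
        truth.graph.to_json(outdir / "simulated" / "graph.json")
    report["input"] = {"n_genes": em.n_genes, "n_cells": em.n_cells}

    # ---- stage: qc --------------------------------------------------------
    em_qc, cell_report = qc.cell_qc(em, config.min_genes, config.max_genes, config.max_mito)
    em_qc = qc.gene_filter(em_qc, config.min_cells_gene)
    cell_report.per_cell.to_csv(outdir / "qc_cells.tsv", sep="\t", index=False)
    report["qc"] = cell_report.summary()
    report["qc"]["n_genes_detected"] = em_qc.n_genes
    if em_qc.n_cells == 0:
        raise DataError("stage qc: no cell passed the filters")

    # ---- stage: normalize + DE --------------------------------------------
    logmat, censored = ltmg.log_normalize(em_qc)
    ga, gb = config.deg_groups
    present = set(em_qc.cell_condition)
    if ga not in present or gb not in present:
        raise DataError(f"stage deg: groups {config.deg_groups} not present in data")
    mask = np.isin(em_qc.cell_condition, [ga, gb])
    deg = ltmg.deg_test(
        logmat[:, mask], censored[:, mask], em_qc.cell_condition[mask],
        kmax=config.kmax, group_order=(ga, gb),
    )
    deg["gene"] = em_qc.gene_ids
    deg.to_csv(outdir / "deg.tsv", sep="\t", index=False)
    sig = deg["q_value"] < config.fdr_alpha
    report["deg"] = {
        "group_a": ga, "group_b": gb,
        "n_tested": int(deg["p_value"].notna().sum()),
        "n_up": int((sig & (deg["direction"] == "up")).sum()),
        "n_down": int((sig & (deg["direction"] == "down")).sum()),
    }

    # ---- stage: states + mebf ---------------------------------------------
    fits = ltmg.fit_all_genes(logmat, censored, kmax=config.kmax)
    states = ltmg.infer_state_matrix(logmat, censored, fits)
    all_modules = []
    for mode in ("activated", "suppressed"):
        B = mebf.binarize_states(states, fits, mode)
        F = mebf.mebf_factorize(B, rank_budget=config.rank_budget, t=config.mebf_t)
        all_modules.extend(
            mebf.modules_from_factorization(
                F, em_qc.gene_ids, em_qc.cell_ids, em_qc.cell_condition, mode=mode
            )
        )
    mebf.modules_table(all_modules).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    report["modules"] = {"n_modules": len(all_modules)}

    # ---- stage: enrichment ------------------------------------------------
    background = list(em_qc.gene_ids)
    if config.pathways_gmt:
        pathways = enr.read_gmt(config.pathways_gmt)
    elif truth is not None:
        psets, tsets = synthetic.truth_gene_sets(truth, seed=config.seed)
        pathways = enr.GeneSetCollection({k: v for k, v in psets.items()})
        if not config.tf_gmt:
            tf_sets = enr.GeneSetCollection(tsets, source="tf_targets")
    else:
        pathways = None
    if config.tf_gmt:
        tf_sets = enr.read_gmt(config.tf_gmt, source="tf_targets")
    elif truth is None:
        tf_sets = None

    if pathways is not None:
        up = deg.loc[sig & (deg["direction"] == "up"), "gene"].tolist()
        down = deg.loc[sig & (deg["direction"] == "down"), "gene"].tolist()
        res_up = enr.enrich(up, pathways, background, alpha=config.enrich_alpha) if up else pd.DataFrame()
        res_down = enr.enrich(down, pathways, background, alpha=config.enrich_alpha) if down else pd.DataFrame()
        res_up.to_csv(outdir / "enrichment_up.tsv", sep="\t", index=False)
        res_down.to_csv(outdir / "enrichment_down.tsv", sep="\t", index=False)
        report["enrichment"] = {
            "n_up_hits": int(res_up["significant"].sum()) if len(res_up) else 0,
            "n_down_hits": int(res_down["significant"].sum()) if len(res_down) else 0,
        }
    if tf_sets is not None and all_modules:
        reg = enr.annotate_modules(all_modules, tf_sets, background, alpha=config.enrich_alpha)
        reg.to_csv(outdir / "regulators.tsv", sep="\t", index=False)
        report["regulators"] = {"n_annotated": int(reg["tf"].notna().sum())}

    # ---- stage: flux ------------------------------------------------------
    graph = None
    if config.graph_json:
        graph = flx.MetabolicModuleGraph.from_json(config.graph_json)
    elif truth is not None:
        graph = truth.graph
    if graph is not None:
        act = flx.module_activity(logmat, em_qc.gene_ids, graph)
        fm = flx.estimate_flux(act, graph, lam=config.flux_lambda, cell_ids=em_qc.cell_ids)
        fm.f.to_csv(outdir / "flux.tsv", sep="\t")
        fa, fb = config.flux_groups
        if fa in present and fb in present:
            fmask = np.isin(em_qc.cell_condition, [fa, fb])
            sub = flx.FluxMatrix(
                f=fm.f.loc[fmask], lam=fm.lam, imbalance=fm.imbalance.loc[fmask]
            )
            cmp_tab = flx.compare_group_flux(
                sub, em_qc.cell_condition[fmask], graph, group_order=(fa, fb)
            )
            cmp_tab.to_csv(outdir / "flux_compare.tsv", sep="\t", index=False)
            report["flux"] = {
                "n_modules_flagged": int(len(cmp_tab)),
                "n_higher_in_a": int((cmp_tab["direction"] == f"{fa} higher").sum()),
                "group_a": fa, "group_b": fb,
            }

    # ---- stage: proteomics ------------------------------------------------
    pm = None
    if config.proteins_dir:
        pm = proteomics.ProteinMatrix.read(config.proteins_dir)
    elif truth is not None:
        pm = synthetic.generate_proteomics(truth, seed=config.seed)
        pm.write(outdir / "simulated_proteomics")
    if pm is not None:
        da, db = config.dep_groups
        dep = proteomics.dep_test(pm, da, db, alpha=config.dep_alpha)
        dep.to_csv(outdir / "dep.tsv", sep="\t", index=False)
        conc = proteomics.rna_protein_concordance(
            deg, dep, rna_alpha=config.fdr_alpha, protein_alpha=config.dep_alpha
        )
        report["proteomics"] = {
            "n_proteins": int(len(dep)),
            "n_up": int((dep["significant"] & (dep["direction"] == "up")).sum()),
            "n_down": int((dep["significant"] & (dep["direction"] == "down")).sum()),
            "concordance": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                            for k, v in conc.items()},
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    (outdir / "report.txt").write_text(format_report(report))
    return report


def format_report(report: dict) -> str:
    lines = [f"scltmg v{report.get('version', '?')} run report", "=" * 34]
    for stage in ("input", "qc", "deg", "modules", "enrichment", "regulators", "flux", "proteomics"):
        if stage in report:
            lines.append(f"[{stage}]")
            for k, v in report[stage].items():
                lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"
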