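"""Synthetic data generator with ground truth for every pipeline stage.

Emulates a two-condition x two-oxygen-state single-cell experiment of the
Fluidigm/Smart-seq2 kind: per-gene log expression follows a left-censored
two-component Gaussian mixture (dropout zeros are censored observations),
a planted fraction of genes carries a condition effect on the active
component, gene x cell co-activation blocks are planted for Boolean
factorization, a small metabolite-module chain graph drives the expression
of its module genes through per-cell ground-truth fluxes, and a matched
proteomics matrix tracks gene-level group means.

Everything is deterministic given ``SyntheticConfig.seed``; sub-generators
draw from independent streams derived from that seed so, e.g., the module
graph is identical whether built standalone or inside ``generate_counts``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .containers import ConfigError, ExpressionMatrix, MetabolicModuleGraph, ProteinMatrix

CONDITIONS = ("Scr", "siRef1")
OXYGEN = ("normoxia", "hypoxia")
GROUPS = tuple(f"{c}_{o}" for c in CONDITIONS for o in OXYGEN)


@dataclass
class GraphSpec:
    """Shape of the synthetic metabolite-module chain graph.

    A chain M0 -> M1 -> ... -> Mn where module r converts M(r-1) into Mr;
    interior metabolites are balanced when all fluxes are equal. All
    modules consume NADP+ by default, mirroring an NADP+-consuming
    reaction panel.
    """

    n_metabolites: int = 16
    n_modules: int = 15
    genes_per_module: int = 5
    frac_nadp: float = 1.0
    flux_low: float = 0.5
    flux_high: float = 2.0
    flux_jitter: float = 0.15
    gene_base: float = 1.0
    gene_slope: float = 1.2
    gene_sd: float = 0.3
    control_flux_scale: float = 1.5


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_cells_per_group: int = 50
    frac_deg: float = 0.1
    effect_size: float = 2.0
    dropout_alpha: float = 0.3
    n_modules: int = 3
    module_size_genes: int = 30
    module_size_cells: int = 20
    noise_flip_rate: float = 0.05
    module_overlap_genes: int = 0
    frac_mito: float = 0.05
    graph_spec: GraphSpec = field(default_factory=GraphSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.graph_spec, dict):
            self.graph_spec = GraphSpec(**self.graph_spec)
        for name in ("frac_deg", "dropout_alpha", "noise_flip_rate", "frac_mito"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} not in [0, 1]")
        for name in ("n_genes", "n_cells_per_group"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_modules < 0:
            raise ConfigError("n_modules must be >= 0")
        if self.n_modules > 0 and (
            self.module_size_genes < 1 or self.module_size_cells < 1
        ):
            raise ConfigError("module block dimensions must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for all planted structure."""

    deg_genes: dict[str, str]
    module_assignments: list[dict]
    true_flux: pd.DataFrame
    gene_mixture_params: dict[str, dict]
    gene_group_means: pd.DataFrame
    graph: MetabolicModuleGraph
    block_flips: list[tuple[str, str]] = field(default_factory=list)
    protein_decoupled: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "deg_genes": self.deg_genes,
            "module_assignments": self.module_assignments,
            "true_flux": {
                "index": list(self.true_flux.index),
                "columns": list(self.true_flux.columns),
                "values": self.true_flux.to_numpy().tolist(),
            },
            "gene_mixture_params": self.gene_mixture_params,
            "block_flips": [list(t) for t in self.block_flips],
            "protein_decoupled": sorted(self.protein_decoupled),
        }
        Path(path).write_text(json.dumps(obj))


# ---------------------------------------------------------------------------
# low-level censored-mixture sampling


def mixture_cdf(x: float, pi, mu, sigma) -> float:
    return float(np.sum(np.asarray(pi) * norm.cdf((x - np.asarray(mu)) / np.asarray(sigma))))


def censoring_point(pi, mu, sigma, alpha: float) -> float:
    """Zcut such that the mixture mass below it equals ``alpha``."""
    if alpha <= 0.0:
        return -np.inf
    lo = min(np.asarray(mu) - 8 * np.asarray(sigma))
    hi = max(np.asarray(mu) + 8 * np.asarray(sigma))
    return brentq(lambda z: mixture_cdf(z, pi, mu, sigma) - alpha, lo, hi)


def sample_censored_mixture(rng, n, pi, mu, sigma, zcut):
    """Draw n values; return (x, censored) with censored x set to 0."""
    pi = np.asarray(pi, dtype=float)
    comp = rng.choice(len(pi), size=n, p=pi / pi.sum())
    x = rng.normal(np.asarray(mu)[comp], np.asarray(sigma)[comp])
    censored = x < zcut
    x = np.where(censored, 0.0, x)
    return x, censored


def truncated_mixture_mean(pi, mu, sigma, zcut) -> float:
    """E[X | X >= zcut] under the mixture — closed-form oracle helper."""
    pi = np.asarray(pi, float)
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    a = (zcut - mu) / sigma
    upper = 1.0 - norm.cdf(a)
    # E[X 1{X>=z}] per component = mu*(1-Phi(a)) + sigma*phi(a)
    num = np.sum(pi * (mu * upper + sigma * norm.pdf(a)))
    den = np.sum(pi * upper)
    return float(num / den)


# ---------------------------------------------------------------------------
# module graph


def generate_module_graph(config: SyntheticConfig) -> tuple[MetabolicModuleGraph, pd.DataFrame]:
    """Build the chain graph and per-cell ground-truth fluxes.

    Fluxes are a per-cell scale (uniform on [flux_low, flux_high]) times a
    per-entry jitter, so the chain is near-balanced within each cell;
    control (Scr) cells get all fluxes multiplied by ``control_flux_scale``.
    """
    spec = config.graph_spec
    if spec.n_modules < 1:
        raise ConfigError("graph_spec.n_modules must be >= 1")
    if spec.n_metabolites < 2 or spec.n_modules < 2:
        raise ConfigError("graph needs >= 2 metabolites and >= 2 modules")

    rng = np.random.default_rng([config.seed, 101])
    n_mod = spec.n_modules
    n_met = max(spec.n_metabolites, n_mod + 1)
    metabolites = [f"M{i}" for i in range(n_met)]
    modules = [f"R{r + 1}" for r in range(n_mod)]
    S = np.zeros((n_met, n_mod))
    for r in range(n_mod):
        S[r, r] = -1.0
        S[r + 1, r] = 1.0
    n_nadp = max(1, int(round(spec.frac_nadp * n_mod)))
    nadp = np.zeros(n_mod, dtype=bool)
    nadp[:n_nadp] = True
    module_genes = {
        m: [f"FX{r + 1}_{i + 1}" for i in range(spec.genes_per_module)]
        for r, m in enumerate(modules)
    }
    graph = MetabolicModuleGraph(
        metabolites=metabolites,
        modules=modules,
        S=S,
        module_genes=module_genes,
        nadp_consumer=nadp,
    )

    cell_ids, groups = _cell_layout(config)
    n_cells = len(cell_ids)
    scale = rng.uniform(spec.flux_low, spec.flux_high, size=n_cells)
    jitter = rng.uniform(1.0 - spec.flux_jitter, 1.0 + spec.flux_jitter, size=(n_cells, n_mod))
    flux = scale[:, None] * jitter
    is_control = np.array([g.startswith("Scr") for g in groups])
    flux[is_control] *= spec.control_flux_scale
    true_flux = pd.DataFrame(flux, index=cell_ids, columns=modules)
    return graph, true_flux


def _cell_layout(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    cell_ids, groups = [], []
    for g in GROUPS:
        for i in range(config.n_cells_per_group):
            cell_ids.append(f"{g}_c{i + 1:03d}")
            groups.append(g)
    return cell_ids, groups


# ---------------------------------------------------------------------------
# expression matrix


def generate_counts(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the counts matrix and the full truth object.

    Per plain gene: a two-component censored Gaussian mixture on the log
    scale; counts = round(exp(x)) (floored at 1) for uncensored draws, 0
    otherwise. Planted DEGs shift the active-component mean by
    +-effect_size in siRef1 cells. Planted co-activation blocks force the
    active component (flip noise forces the suppressed one). Flux-module
    genes are generated as base + slope * flux + noise.
    """
    rng = np.random.default_rng([config.seed, 1])
    cell_ids, groups = _cell_layout(config)
    n_cells = len(cell_ids)
    groups_arr = np.array(groups, dtype=object)
    is_siref = np.array([g.startswith("siRef1") for g in groups_arr])

    n_mito = int(round(config.frac_mito * config.n_genes))
    gene_ids = [f"MT-G{i + 1:04d}" if i < n_mito else f"G{i + 1:04d}" for i in range(config.n_genes)]
    is_mito_base = np.array([g.startswith("MT-") for g in gene_ids])

    # planted DEGs and Boolean blocks drawn from non-mito genes, disjoint
    plain_idx = np.flatnonzero(~is_mito_base)
    rng_plan = np.random.default_rng([config.seed, 2])
    n_deg = int(round(config.frac_deg * config.n_genes))
    chosen = rng_plan.choice(plain_idx, size=n_deg, replace=False) if n_deg else np.array([], int)
    deg_up = chosen[: n_deg // 2]
    deg_down = chosen[n_deg // 2:]
    remaining = np.setdiff1d(plain_idx, chosen)

    block_gene_sets: list[np.ndarray] = []
    block_cell_sets: list[np.ndarray] = []
    block_groups: list[str] = []
    pool = remaining.copy()
    rng_blk = np.random.default_rng([config.seed, 3])
    for b in range(config.n_modules):
        take = config.module_size_genes
        if config.module_overlap_genes and block_gene_sets:
            shared = rng_blk.choice(
                block_gene_sets[-1], size=min(config.module_overlap_genes, len(block_gene_sets[-1])), replace=False
            )
            fresh = rng_blk.choice(pool, size=take - len(shared), replace=False)
            genes_b = np.concatenate([shared, fresh])
        else:
            genes_b = rng_blk.choice(pool, size=take, replace=False)
        pool = np.setdiff1d(pool, genes_b)
        grp = GROUPS[b % len(GROUPS)]
        grp_cells = np.flatnonzero(groups_arr == grp)
        cells_b = rng_blk.choice(grp_cells, size=min(config.module_size_cells, len(grp_cells)), replace=False)
        block_gene_sets.append(np.sort(genes_b))
        block_cell_sets.append(np.sort(cells_b))
        block_groups.append(grp)

    counts = np.zeros((config.n_genes, n_cells), dtype=np.int64)
    mixture_params: dict[str, dict] = {}
    deg_dir: dict[str, str] = {}
    flips: list[tuple[str, str]] = []

    in_block = np.zeros((config.n_genes, n_cells), dtype=np.int8)  # 1 active-forced, -1 flipped
    rng_flip = np.random.default_rng([config.seed, 4])
    for genes_b, cells_b in zip(block_gene_sets, block_cell_sets):
        for gi in genes_b:
            for ci in cells_b:
                if rng_flip.random() < config.noise_flip_rate:
                    in_block[gi, ci] = -1
                else:
                    in_block[gi, ci] = 1

    for i, gid in enumerate(gene_ids):
        pi_low = rng.uniform(0.3, 0.5)
        pi = np.array([pi_low, 1.0 - pi_low])
        mu = np.array([rng.uniform(0.5, 1.5), rng.uniform(3.0, 5.0)])
        sigma = rng.uniform(0.4, 0.8, size=2)
        zcut = censoring_point(pi, mu, sigma, config.dropout_alpha)
        mixture_params[gid] = {
            "K": 2, "pi": pi.tolist(), "mu": mu.tolist(),
            "sigma": sigma.tolist(), "zcut": float(zcut),
        }

        shift = 0.0
        if i in deg_up:
            shift, deg_dir[gid] = config.effect_size, "up"
        elif i in deg_down:
            shift, deg_dir[gid] = -config.effect_size, "down"

        mu_cells = np.tile(mu, (n_cells, 1))
        if shift:
            mu_cells[is_siref, 1] += shift
        comp = (rng.random(n_cells) >= pi[0]).astype(int)
        forced = in_block[i]
        comp = np.where(forced == 1, 1, comp)
        comp = np.where(forced == -1, 0, comp)
        x = rng.normal(mu_cells[np.arange(n_cells), comp], sigma[comp])
        # forced-active block entries are kept above the censoring point
        x = np.where(forced == 1, np.maximum(x, zcut + 0.05), x)
        keep = x >= zcut
        counts[i, keep] = np.maximum(1, np.rint(np.exp(x[keep]))).astype(np.int64)

    for genes_b, cells_b in zip(block_gene_sets, block_cell_sets):
        for gi in genes_b:
            for ci in cells_b:
                if in_block[gi, ci] == -1:
                    flips.append((gene_ids[gi], cell_ids[ci]))

    # flux-module genes appended below the base genes
    graph, true_flux = generate_module_graph(config)
    spec = config.graph_spec
    flux_rows, flux_ids = [], []
    rng_fx = np.random.default_rng([config.seed, 5])
    for r, m in enumerate(graph.modules):
        f = true_flux[m].to_numpy()
        for g in graph.module_genes[m]:
            x = spec.gene_base + spec.gene_slope * f + rng_fx.normal(0.0, spec.gene_sd, size=n_cells)
            row = np.zeros(n_cells, dtype=np.int64)
            keep = x >= 0.05  # near-zero censoring: flux genes are broadly detected
            row[keep] = np.maximum(1, np.rint(np.exp(x[keep]))).astype(np.int64)
            flux_rows.append(row)
            flux_ids.append(g)
            mixture_params[g] = {
                "K": 1, "pi": [1.0], "mu": [spec.gene_base],
                "sigma": [spec.gene_sd], "zcut": 0.05, "flux_module": m,
            }

    all_counts = np.vstack([counts] + [np.array(flux_rows)]) if flux_rows else counts
    all_ids = np.array(gene_ids + flux_ids, dtype=object)
    is_mito = np.concatenate([is_mito_base, np.zeros(len(flux_ids), dtype=bool)])

    em = ExpressionMatrix(
        counts=all_counts,
        gene_ids=all_ids,
        cell_ids=np.array(cell_ids, dtype=object),
        cell_condition=groups_arr,
        is_mito=is_mito,
    )

    # group means on the CPM log scale the pipeline analyzes, so the
    # matched proteomics matrix tracks the same quantity the DE test sees
    totals = all_counts.sum(axis=0).astype(float)
    logc = np.log1p(all_counts * (1e6 / np.maximum(totals, 1.0))[None, :])
    ggm = pd.DataFrame(
        {g: logc[:, groups_arr == g].mean(axis=1) for g in GROUPS}, index=all_ids
    )

    truth = SyntheticTruth(
        deg_genes=deg_dir,
        module_assignments=[
            {
                "genes": [gene_ids[g] for g in gs],
                "cells": [cell_ids[c] for c in cs],
                "group": grp,
                "mode": "activated",
            }
            for gs, cs, grp in zip(block_gene_sets, block_cell_sets, block_groups)
        ],
        true_flux=true_flux,
        gene_mixture_params=mixture_params,
        gene_group_means=ggm,
        graph=graph,
        block_flips=flips,
    )
    return em, truth


# ---------------------------------------------------------------------------
# standalone Boolean block generator (for factorization experiments)


def generate_boolean_blocks(
    n_genes: int,
    n_cells: int,
    blocks: list[tuple[int, int]],
    flip_rate: float = 0.0,
    seed: int = 0,
    overlap_genes: int = 0,
):
    """Plant rank-1 blocks in a binary matrix; flip entries at flip_rate.

    ``blocks`` is a list of (n_block_genes, n_block_cells). Returns
    (matrix uint8, list of (gene_index_array, cell_index_array)).
    Flip noise toggles entries uniformly over the whole matrix.
    """
    rng = np.random.default_rng(seed)
    M = np.zeros((n_genes, n_cells), dtype=np.uint8)
    truth = []
    gene_cursor = 0
    cell_cursor = 0
    for bi, (bg, bc) in enumerate(blocks):
        g0 = max(0, gene_cursor - (overlap_genes if bi else 0))
        gidx = np.arange(g0, g0 + bg) % n_genes
        cidx = np.arange(cell_cursor, cell_cursor + bc) % n_cells
        M[np.ix_(gidx, cidx)] = 1
        truth.append((gidx.copy(), cidx.copy()))
        gene_cursor = g0 + bg
        cell_cursor += bc
    if flip_rate > 0:
        flips = rng.random(M.shape) < flip_rate
        M = np.where(flips, 1 - M, M).astype(np.uint8)
    return M, truth


# ---------------------------------------------------------------------------
# proteomics


def generate_proteomics(
    truth: SyntheticTruth,
    n_replicates: int = 6,
    noise_sd: float = 0.3,
    decoupled_frac: float = 0.2,
    seed: int = 0,
    n_proteins: int | None = None,
) -> ProteinMatrix:
    """Protein abundances = gene-level group mean + Gaussian noise.

    A ``decoupled_frac`` fraction of proteins has its group-mean vector
    randomly permuted across groups, severing the RNA-protein link.
    Decoupled protein ids are recorded on ``truth.protein_decoupled``.
    """
    if n_replicates < 2:
        raise ConfigError("need >= 2 replicates per group for a group test")
    rng = np.random.default_rng([seed, 7])
    ggm = truth.gene_group_means
    genes = list(ggm.index)
    if n_proteins is not None:
        genes = genes[: n_proteins]
    prot_ids = [f"P_{g}" for g in genes]
    n_dec = int(round(decoupled_frac * len(genes)))
    dec_idx = set(rng.choice(len(genes), size=n_dec, replace=False).tolist()) if n_dec else set()

    sample_ids, sample_group = [], []
    for g in GROUPS:
        for r in range(n_replicates):
            sample_ids.append(f"{g}_rep{r + 1}")
            sample_group.append(g)
    group_col = {g: j for j, g in enumerate(GROUPS)}

    means = ggm.loc[genes, list(GROUPS)].to_numpy().copy()
    decoupled: set[str] = set()
    for i in dec_idx:
        means[i] = means[i, rng.permutation(len(GROUPS))]
        decoupled.add(prot_ids[i])
    truth.protein_decoupled = decoupled

    ab = np.empty((len(genes), len(sample_ids)))
    for s, g in enumerate(sample_group):
        ab[:, s] = means[:, group_col[g]]
    if noise_sd > 0:
        ab = ab + rng.normal(0.0, noise_sd, size=ab.shape)
    return ProteinMatrix(
        abundance=ab,
        protein_ids=np.array(prot_ids, dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        sample_group=np.array(sample_group, dtype=object),
        protein_gene=dict(zip(prot_ids, genes)),
    )


def truth_gene_sets(truth: SyntheticTruth, n_random: int = 20, set_size: int = 30, seed: int = 0):
    """Gene-set collections derived from the truth, for enrichment runs.

    Returns (pathway_sets, tf_sets): pathway_sets contains the planted
    up/down DEG sets plus random sets; tf_sets contains one "TF target"
    set per planted module plus random sets.
    """
    rng = np.random.default_rng([seed, 8])
    universe = list(truth.gene_group_means.index)
    pathways = {
        "PLANTED_UP": sorted(g for g, d in truth.deg_genes.items() if d == "up"),
        "PLANTED_DOWN": sorted(g for g, d in truth.deg_genes.items() if d == "down"),
    }
    for i in range(n_random):
        pathways[f"RANDOM_SET_{i + 1}"] = sorted(
            rng.choice(universe, size=set_size, replace=False).tolist()
        )
    tfs = {}
    for j, mod in enumerate(truth.module_assignments):
        tfs[f"TF{j + 1}_TARGETS"] = sorted(mod["genes"])
    for i in range(n_random):
        tfs[f"TF_RANDOM_{i + 1}"] = sorted(
            rng.choice(universe, size=set_size, replace=False).tolist()
        )
    pathways = {k: v for k, v in pathways.items() if v}
    return pathways, tfs
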