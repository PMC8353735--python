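"""Differential protein abundance and RNA-protein concordance.

Group comparison is a two-sided Mann-Whitney rank-sum test per protein:
for combined sample sizes n <= 12 the permutation null of the U statistic
is enumerated exactly (midranks make it tie-safe), otherwise the normal
approximation with tie correction is used. Significance is thresholded on
the raw p-value (default alpha = 0.01). Concordance with an RNA DEG table
is summarized as the sign-agreement fraction among gene-protein pairs
significant on both sides plus a hypergeometric overlap test.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .containers import ConfigError, ProteinMatrix
from .enrichment import hypergeom_test

EXACT_MAX_N = 12


def _u_stat(ranks: np.ndarray, idx: tuple[int, ...], n1: int, total_rank_base: float) -> float:
    return float(ranks[list(idx)].sum()) - total_rank_base


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact enumeration when len(x)+len(y) <= 12.

    The exact branch enumerates all C(n, n1) group assignments of the
    pooled midranks, so ties are handled as a true permutation test; the
    two-sided p is 2 * min(P(U <= u), P(U >= u)) capped at 1, matching the
    standard exact-test convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ConfigError("each group needs >= 2 samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if n1 + n2 <= EXACT_MAX_N:
        ranks = rankdata(pooled)
        base = n1 * (n1 + 1) / 2.0
        u_obs = float(ranks[:n1].sum()) - base
        n = n1 + n2
        us = np.fromiter(
            (_u_stat(ranks, idx, n1, base) for idx in combinations(range(n), n1)),
            dtype=float,
            count=comb(n, n1),
        )
        eps = 1e-9
        lo = np.mean(us <= u_obs + eps)
        hi = np.mean(us >= u_obs - eps)
        return float(min(1.0, 2.0 * min(lo, hi)))
    return float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def dep_test(
    pm: ProteinMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-protein Mann-Whitney comparison of two sample groups."""
    a_mask = pm.sample_group == group_a
    b_mask = pm.sample_group == group_b
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ConfigError("each group needs >= 2 samples")
    rows = []
    for i, pid in enumerate(pm.protein_ids):
        xa = pm.abundance[i, a_mask]
        xb = pm.abundance[i, b_mask]
        p = mann_whitney_p(xa, xb)
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        direction = "up" if med_a > med_b else ("down" if med_a < med_b else "none")
        rows.append(
            {
                "protein": pid,
                "gene": pm.protein_gene.get(pid),
                "p_value": p,
                "direction": direction,
                "median_a": med_a,
                "median_b": med_b,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def rna_protein_concordance(
    deg: pd.DataFrame,
    dep: pd.DataFrame,
    rna_alpha: float = 0.05,
    protein_alpha: float = 0.01,
) -> dict:
    """Sign agreement and overlap significance of RNA and protein calls.

    ``deg`` needs columns gene / q_value / direction; ``dep`` needs
    gene / p_value / direction (protein rows with no gene mapping are
    ignored). Overlap p is hypergeometric over the mapped-gene universe.
    """
    dep = dep.dropna(subset=["gene"])
    mapped = set(deg["gene"]) & set(dep["gene"])
    if not mapped:
        warnings.warn("no gene is shared between the DEG and DEP tables", stacklevel=2)
        return {"n_universe": 0, "n_both_significant": 0,
                "sign_agreement": np.nan, "overlap_p": np.nan}
    deg_m = deg[deg["gene"].isin(mapped)].set_index("gene")
    dep_m = dep[dep["gene"].isin(mapped)].groupby("gene").first()
    rna_sig = set(deg_m.index[deg_m["q_value"] < rna_alpha])
    prot_sig = set(dep_m.index[dep_m["p_value"] < protein_alpha])
    both = sorted(rna_sig & prot_sig)
    if both:
        agree = float(
            np.mean([deg_m.loc[g, "direction"] == dep_m.loc[g, "direction"] for g in both])
        )
    else:
        warnings.warn("no gene is significant in both tables", stacklevel=2)
        agree = np.nan
    N = len(mapped)
    p = hypergeom_test(len(both), len(rna_sig), len(prot_sig), N) if both else 1.0
    return {
        "n_universe": N,
        "n_rna_significant": len(rna_sig),
        "n_protein_significant": len(prot_sig),
        "n_both_significant": len(both),
        "sign_agreement": agree,
        "overlap_p": p,
    }
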