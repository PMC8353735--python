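"""Greedy Boolean matrix factorization for gene co-regulation modules.

A binarized expression-state matrix (genes x cells, 1 = consistently
activated or suppressed) is approximated by the Boolean product of a
genes x r pattern matrix U and an r x cells matrix V. Rank-1 patterns are
extracted greedily with a median-expansion heuristic: seed with the column
(or row) whose nonzero count is the median among nonzero columns, expand
to all columns that overlap the seed on at least a fraction t of its ones,
refine, and accept the pattern if it covers more uncovered ones than zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .containers import DataError


@dataclass
class BooleanFactorization:
    U: np.ndarray  # genes x r
    V: np.ndarray  # r x cells
    gains: list[int] = field(default_factory=list)
    error: int = 0

    @property
    def r(self) -> int:
        return self.U.shape[1]


def binarize_states(states: np.ndarray, fits, mode: str) -> np.ndarray:
    """Binary matrix from a StateMatrix.

    mode="activated": 1 iff the cell is in the gene's highest-mean
    component (requires K >= 2; a K=1 gene has no activated state).
    mode="suppressed": 1 iff the cell is in state 0.
    """
    if mode not in ("activated", "suppressed"):
        raise DataError(f"unknown mode {mode!r}")
    states = np.asarray(states)
    out = np.zeros(states.shape, dtype=np.uint8)
    for i, fit in enumerate(fits):
        if mode == "activated":
            if fit.K >= 2:
                out[i] = states[i] == fit.K - 1
        else:
            out[i] = states[i] == 0
    return out


def _expand_from_column(M: np.ndarray, seed_col: np.ndarray, t: float):
    """One candidate (u, v) grown from a seed column, refined twice."""
    u = seed_col.astype(bool)
    if not u.any():
        return None
    for _ in range(2):
        nu = int(u.sum())
        overlap = M[u].sum(axis=0)  # per column, ones matching u
        v = overlap >= t * nu
        if not v.any():
            return None
        nv = int(v.sum())
        u = M[:, v].sum(axis=1) >= t * nv
        if not u.any():
            return None
    overlap = M[u].sum(axis=0)
    v = overlap >= t * int(u.sum())
    if not v.any():
        return None
    return u, v


def _gain(R: np.ndarray, u: np.ndarray, v: np.ndarray) -> int:
    """(residual ones covered) - (residual zeros covered)."""
    block = R[np.ix_(u, v)]
    ones = int(block.sum())
    zeros = int(block.size - ones)
    return ones - zeros


def _median_seed_index(counts: np.ndarray) -> int:
    """Index whose nonzero count is the (upper) median among nonzero entries."""
    nz = np.flatnonzero(counts > 0)
    order = nz[np.argsort(counts[nz], kind="stable")]
    return int(order[len(order) // 2])


def rank1_pattern(M_residual: np.ndarray, t: float = 0.8):
    """Best rank-1 Boolean pattern from column- and row-seeded passes.

    Returns (u, v, gain) as boolean vectors, or None when the residual has
    no ones or no candidate survives expansion.
    """
    R = np.asarray(M_residual).astype(np.uint8)
    if R.sum() == 0:
        return None
    candidates = []
    col_counts = R.sum(axis=0)
    if (col_counts > 0).any():
        j = _median_seed_index(col_counts)
        cand = _expand_from_column(R, R[:, j], t)
        if cand is not None:
            candidates.append(cand)
    row_counts = R.sum(axis=1)
    if (row_counts > 0).any():
        i = _median_seed_index(row_counts)
        cand = _expand_from_column(R.T, R[i, :], t)
        if cand is not None:
            candidates.append((cand[1], cand[0]))  # transpose back
    if not candidates:
        return None
    best = max(candidates, key=lambda uv: _gain(R, uv[0], uv[1]))
    u, v = best
    return u, v, _gain(R, u, v)


def mebf_factorize(M: np.ndarray, rank_budget: int = 10, t: float = 0.8) -> BooleanFactorization:
    """Extract up to ``rank_budget`` rank-1 patterns with positive gain."""
    M = np.asarray(M).astype(np.uint8)
    if not np.isin(M, (0, 1)).all():
        raise DataError("input must be binary")
    R = M.copy()
    us, vs, gains = [], [], []
    for _ in range(rank_budget):
        res = rank1_pattern(R, t)
        if res is None:
            break
        u, v, g = res
        if g <= 0:
            break
        us.append(u)
        vs.append(v)
        gains.append(g)
        R[np.ix_(u, v)] = 0
    r = len(us)
    U = np.column_stack(us).astype(np.uint8) if r else np.zeros((M.shape[0], 0), np.uint8)
    V = np.vstack(vs).astype(np.uint8) if r else np.zeros((0, M.shape[1]), np.uint8)
    recon = (U @ V > 0).astype(np.uint8)
    error = int(np.sum(M != recon))
    return BooleanFactorization(U=U, V=V, gains=gains, error=error)


def modules_from_factorization(
    F: BooleanFactorization,
    gene_ids: np.ndarray,
    cell_ids: np.ndarray,
    cell_condition: np.ndarray | None = None,
    mode: str = "activated",
) -> list[dict]:
    """Per-pattern gene/cell sets with a Fisher condition-association test.

    With more than two condition levels, each level is tested one-vs-rest
    and the strongest association is reported.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    cell_ids = np.asarray(cell_ids, dtype=object)
    modules = []
    for r in range(F.r):
        u = F.U[:, r].astype(bool)
        v = F.V[r].astype(bool)
        if not u.any() or not v.any():
            continue
        entry = {
            "module": f"{mode}_{r + 1}",
            "mode": mode,
            "genes": list(gene_ids[u]),
            "cells": list(cell_ids[v]),
            "gain": F.gains[r] if r < len(F.gains) else None,
        }
        if cell_condition is not None:
            cond = np.asarray(cell_condition, dtype=object)
            best = None
            for level in sorted(set(cond)):
                in_lvl = cond == level
                table = [
                    [int(np.sum(v & in_lvl)), int(np.sum(v & ~in_lvl))],
                    [int(np.sum(~v & in_lvl)), int(np.sum(~v & ~in_lvl))],
                ]
                odds, p = fisher_exact(table, alternative="two-sided")
                if best is None or p < best[1]:
                    best = (level, p, odds)
            entry["assoc_condition"], entry["assoc_p"], entry["assoc_odds"] = best
        modules.append(entry)
    return modules


def modules_table(modules: list[dict]) -> pd.DataFrame:
    rows = [
        {
            "module": m["module"],
            "mode": m["mode"],
            "n_genes": len(m["genes"]),
            "n_cells": len(m["cells"]),
            "gain": m["gain"],
            "assoc_condition": m.get("assoc_condition"),
            "assoc_p": m.get("assoc_p"),
            "genes": ",".join(map(str, m["genes"])),
            "cells": ",".join(map(str, m["cells"])),
        }
        for m in modules
    ]
    return pd.DataFrame(rows)
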