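"""Cell- and gene-level quality-control filters.

Cells are excluded when they express fewer than ``min_genes`` or more than
``max_genes`` nonzero genes, or when more than ``max_mito`` of their counts
map to mitochondrial genes (strict inequalities: a cell exactly at a
threshold is retained). Genes are kept when nonzero in at least
``min_cells`` retained cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigError, ExpressionMatrix


@dataclass
class CellQCReport:
    per_cell: pd.DataFrame  # cell_id, condition, n_genes, mito_frac, reason
    retained_by_group: pd.Series
    n_input: int
    n_retained: int

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def summary(self) -> dict:
        reasons = self.per_cell["reason"].value_counts().to_dict()
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "excluded_by_reason": {k: int(v) for k, v in reasons.items() if k != "none"},
            "retained_by_group": {k: int(v) for k, v in self.retained_by_group.items()},
        }


def cell_qc(
    m: ExpressionMatrix,
    min_genes: int = 250,
    max_genes: int = 10000,
    max_mito: float = 0.15,
) -> tuple[ExpressionMatrix, CellQCReport]:
    """Filter cells; record exactly one exclusion reason per cell.

    Reasons are checked in the order low_genes, high_genes, high_mito;
    the first failing rule is recorded.
    """
    if min_genes < 0 or max_genes <= 0 or not (0.0 < max_mito <= 1.0):
        raise ConfigError("invalid QC thresholds")
    n_nonzero = (m.counts > 0).sum(axis=0)
    totals = m.counts.sum(axis=0)
    mito_counts = m.counts[m.is_mito].sum(axis=0) if m.is_mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    reason = np.full(m.n_cells, "none", dtype=object)
    reason[np.asarray(n_nonzero < min_genes)] = "low_genes"
    high = (reason == "none") & np.asarray(n_nonzero > max_genes)
    reason[high] = "high_genes"
    mito_bad = (reason == "none") & (mito_frac > max_mito)
    reason[mito_bad] = "high_mito"

    keep = reason == "none"
    per_cell = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "condition": m.cell_condition,
            "n_genes": np.asarray(n_nonzero, dtype=int),
            "mito_frac": mito_frac,
            "reason": reason,
        }
    )
    retained_by_group = per_cell.loc[keep].groupby("condition").size()
    if not keep.any():
        warnings.warn("cell_qc excluded every cell", stacklevel=2)
    report = CellQCReport(
        per_cell=per_cell,
        retained_by_group=retained_by_group,
        n_input=m.n_cells,
        n_retained=int(keep.sum()),
    )
    return m.subset_cells(keep), report


def gene_filter(m: ExpressionMatrix, min_cells: int = 2) -> ExpressionMatrix:
    """Keep genes nonzero in at least ``min_cells`` cells."""
    if min_cells <= 0:
        return m
    keep = (m.counts > 0).sum(axis=1) >= min_cells
    return m.subset_genes(np.asarray(keep))
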