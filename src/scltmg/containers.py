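"""In-memory containers and plain-text I/O for the pipeline.

The central object is :class:`ExpressionMatrix`, a genes x cells raw count
matrix with the two annotations every downstream stage needs: the
experimental condition of each cell and a mitochondrial flag per gene.
Matrices round-trip through MatrixMarket (MTX) with TSV sidecars so any
stage can be re-run from files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ConfigError(ValueError):
    """Invalid configuration (bad thresholds, fractions, shapes)."""


class DataError(ValueError):
    """Invalid or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Raw counts, genes in rows, cells in columns.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape (n_genes, n_cells).
    gene_ids, cell_ids
        Unique string identifiers for rows / columns.
    cell_condition
        Condition label per cell (e.g. ``"siRef1_hypoxia"``).
    is_mito
        Boolean flag per gene marking mitochondrial genes.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_condition: np.ndarray
    is_mito: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_condition = np.asarray(self.cell_condition, dtype=object)
        self.is_mito = np.asarray(self.is_mito, dtype=bool)
        self.validate()

    def validate(self) -> None:
        g, c = self.counts.shape
        if len(self.gene_ids) != g or len(self.is_mito) != g:
            raise DataError("gene annotation length does not match matrix rows")
        if len(self.cell_ids) != c or len(self.cell_condition) != c:
            raise DataError("cell annotation length does not match matrix columns")
        if len(set(self.gene_ids)) != g:
            raise DataError("gene ids are not unique")
        if len(set(self.cell_ids)) != c:
            raise DataError("cell ids are not unique")
        if self.counts.size and self.counts.min() < 0:
            raise DataError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(
            counts=self.counts[:, mask],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[mask],
            cell_condition=self.cell_condition[mask],
            is_mito=self.is_mito,
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(
            counts=self.counts[mask, :],
            gene_ids=self.gene_ids[mask],
            cell_ids=self.cell_ids,
            cell_condition=self.cell_condition,
            is_mito=self.is_mito[mask],
        )

    # ---- plain-text round trip -------------------------------------------

    def write(self, outdir: str | Path) -> None:
        """Write counts.mtx plus genes.tsv / cells.tsv sidecars."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(outdir / "counts.mtx"), sparse.csr_matrix(self.counts))
        pd.DataFrame(
            {"gene_id": self.gene_ids, "is_mito": self.is_mito.astype(int)}
        ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"cell_id": self.cell_ids, "condition": self.cell_condition}
        ).to_csv(outdir / "cells.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "ExpressionMatrix":
        indir = Path(indir)
        return read_expression_matrix(
            indir / "counts.mtx", indir / "cells.tsv", indir / "genes.tsv"
        )


def read_expression_matrix(
    counts_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path | None = None,
    mito_prefix: str = "MT-",
) -> ExpressionMatrix:
    """Load an :class:`ExpressionMatrix` from MTX (or dense TSV) + sidecars.

    When the genes sidecar lacks an ``is_mito`` column (or no sidecar is
    given for a dense TSV with gene-id index), mitochondrial genes are
    flagged by the conventional ``MT-`` symbol prefix.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        counts = np.asarray(spio.mmread(str(counts_path)).todense())
        if genes_path is None:
            raise DataError("MTX input requires a genes sidecar")
        genes = pd.read_csv(genes_path, sep="\t")
        gene_ids = genes["gene_id"].astype(str).to_numpy()
    else:
        dense = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = dense.to_numpy()
        gene_ids = dense.index.astype(str).to_numpy()
        genes = None
        if genes_path is not None:
            genes = pd.read_csv(genes_path, sep="\t")
            gene_ids = genes["gene_id"].astype(str).to_numpy()
    cells = pd.read_csv(cells_path, sep="\t")
    if counts.shape != (len(gene_ids), len(cells)):
        raise DataError(
            f"matrix shape {counts.shape} does not match sidecars "
            f"({len(gene_ids)} genes, {len(cells)} cells)"
        )
    if genes is not None and "is_mito" in genes.columns:
        is_mito = genes["is_mito"].astype(bool).to_numpy()
    else:
        is_mito = np.array([g.startswith(mito_prefix) for g in gene_ids])
    return ExpressionMatrix(
        counts=np.rint(counts).astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=cells["cell_id"].astype(str).to_numpy(),
        cell_condition=cells["condition"].astype(str).to_numpy(),
        is_mito=is_mito,
    )


@dataclass
class MetabolicModuleGraph:
    """Metabolite-module stoichiometry with module gene sets.

    ``S`` is the signed metabolites x modules stoichiometric matrix
    (positive = produced, negative = consumed). ``nadp_consumer`` flags
    the modules whose reaction consumes NADP+.
    """

    metabolites: list[str]
    modules: list[str]
    S: np.ndarray
    module_genes: dict[str, list[str]]
    nadp_consumer: np.ndarray
    exchange: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.nadp_consumer = np.asarray(self.nadp_consumer, dtype=bool)
        if self.exchange is None:
            self.exchange = np.zeros(len(self.modules), dtype=bool)
        self.exchange = np.asarray(self.exchange, dtype=bool)
        if self.S.shape != (len(self.metabolites), len(self.modules)):
            raise DataError("stoichiometry shape mismatch")
        for i, m in enumerate(self.modules):
            if not self.module_genes.get(m):
                raise DataError(f"module {m} has no genes")
            if not self.exchange[i] and not np.any(self.S[:, i]):
                raise DataError(f"module {m} has all-zero stoichiometry")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "metabolites": self.metabolites,
            "modules": self.modules,
            "S": self.S.tolist(),
            "module_genes": self.module_genes,
            "nadp_consumer": self.nadp_consumer.astype(int).tolist(),
            "exchange": self.exchange.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicModuleGraph":
        obj = json.loads(Path(path).read_text())
        return cls(
            metabolites=obj["metabolites"],
            modules=obj["modules"],
            S=np.asarray(obj["S"], dtype=float),
            module_genes=obj["module_genes"],
            nadp_consumer=np.asarray(obj["nadp_consumer"], dtype=bool),
            exchange=np.asarray(obj.get("exchange", []), dtype=bool)
            if obj.get("exchange")
            else None,
        )


@dataclass
class ProteinMatrix:
    """Protein abundances, proteins x samples, with group labels."""

    abundance: np.ndarray
    protein_ids: np.ndarray
    sample_ids: np.ndarray
    sample_group: np.ndarray
    protein_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.sample_group = np.asarray(self.sample_group, dtype=object)
        p, s = self.abundance.shape
        if len(self.protein_ids) != p:
            raise DataError("protein ids do not match matrix rows")
        if len(self.sample_ids) != s or len(self.sample_group) != s:
            raise DataError("sample annotations do not match matrix columns")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            self.abundance, index=self.protein_ids, columns=self.sample_ids
        )
        df.index.name = "protein_id"
        df.to_csv(outdir / "proteins.tsv", sep="\t")
        pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.sample_group}
        ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "protein_id": list(self.protein_gene.keys()),
                "gene_id": list(self.protein_gene.values()),
            }
        ).to_csv(outdir / "protein_gene.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "ProteinMatrix":
        indir = Path(indir)
        df = pd.read_csv(indir / "proteins.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(indir / "samples.tsv", sep="\t")
        mapping_path = indir / "protein_gene.tsv"
        mapping: dict[str, str] = {}
        if mapping_path.exists():
            mdf = pd.read_csv(mapping_path, sep="\t")
            mapping = dict(zip(mdf["protein_id"].astype(str), mdf["gene_id"].astype(str)))
        return cls(
            abundance=df.to_numpy(),
            protein_ids=df.index.astype(str).to_numpy(),
            sample_ids=samples["sample_id"].astype(str).to_numpy(),
            sample_group=samples["group"].astype(str).to_numpy(),
            protein_gene=mapping,
        )
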