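#!/usr/bin/env python
"""Apply the cell and gene quality filters to the simulated dataset.

Cells with fewer than 250 or more than 10,000 nonzero genes, or more than
15% mitochondrial counts, are excluded; genes detected in fewer than two
retained cells are dropped. Writes the filtered matrix and the per-cell
QC report under results/qc/.
"""

import json
from pathlib import Path

from scltmg import qc
from scltmg.containers import ExpressionMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    em = ExpressionMatrix.read(ROOT / "sim")
    filtered, report = qc.cell_qc(em, min_genes=250, max_genes=10_000, max_mito=0.15)
    filtered = qc.gene_filter(filtered, min_cells=2)
    out = ROOT / "qc"
    filtered.write(out)
    report.per_cell.to_csv(out / "qc_cells.tsv", sep="\t", index=False)
    (out / "qc_summary.json").write_text(json.dumps(report.summary(), indent=1))
    excluded = report.summary()["excluded_by_reason"] or "none"
    print(f"retained {report.n_retained}/{report.n_input} cells "
          f"(excluded: {excluded}), {filtered.n_genes} genes detected")


if __name__ == "__main__":
    main()
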