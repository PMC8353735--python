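#!/usr/bin/env python
"""Differential protein abundance and RNA-protein concordance.

Mann-Whitney comparison (exact for small samples) of knockdown vs control
proteomes at raw p < 0.01, then sign-concordance of the protein calls
with the scRNA-seq DEG table. Writes results under results/proteomics/.
"""

import json
from pathlib import Path

import pandas as pd

from scltmg import proteomics
from scltmg.containers import ProteinMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"
GROUPS = ("siRef1_hypoxia", "Scr_hypoxia")


def main() -> None:
    pm = ProteinMatrix.read(ROOT / "sim" / "proteomics")
    dep = proteomics.dep_test(pm, *GROUPS, alpha=0.01)
    out = ROOT / "proteomics"
    out.mkdir(parents=True, exist_ok=True)
    dep.to_csv(out / "dep.tsv", sep="\t", index=False)
    sig = dep[dep["significant"]]
    print(f"{int((sig['direction'] == 'up').sum())} upregulated and "
          f"{int((sig['direction'] == 'down').sum())} downregulated proteins "
          f"at p < 0.01 ({GROUPS[0]} vs {GROUPS[1]})")

    deg = pd.read_csv(ROOT / "deg" / "deg.tsv", sep="\t")
    conc = proteomics.rna_protein_concordance(deg, dep)
    (out / "concordance.json").write_text(json.dumps(conc, indent=1, default=float))
    print(f"gene-protein pairs significant in both: {conc['n_both_significant']}; "
          f"sign agreement {conc['sign_agreement']:.1%} "
          f"(overlap p = {conc['overlap_p']:.2e})")


if __name__ == "__main__":
    main()
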