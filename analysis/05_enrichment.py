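#!/usr/bin/env python
"""Hypergeometric pathway enrichment of the up- and down-regulated genes.

Uses the detected-gene universe as background and truth-derived gene-set
collections (planted DEG sets plus random sets) as a stand-in for a
canonical-pathway GMT; significance at raw p < 0.001. Writes enrichment
tables under results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from scltmg import enrichment as enr
from scltmg import synthetic as syn
from scltmg.containers import ExpressionMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    em = ExpressionMatrix.read(ROOT / "qc")
    deg = pd.read_csv(ROOT / "deg" / "deg.tsv", sep="\t")
    sig = deg[deg["q_value"] < 0.05]
    up = sig.loc[sig["direction"] == "up", "gene"].tolist()
    down = sig.loc[sig["direction"] == "down", "gene"].tolist()

    cfg = syn.SyntheticConfig(seed=1)
    _, truth = syn.generate_counts(cfg)
    psets, _ = syn.truth_gene_sets(truth, seed=1)
    collection = enr.GeneSetCollection(psets)
    background = list(em.gene_ids)

    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    for name, query in (("up", up), ("down", down)):
        res = enr.enrich(query, collection, background, alpha=0.001)
        res.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
        hits = res[res["significant"]]
        print(f"{name}-regulated ({len(query)} genes): "
              f"{len(hits)} sets at p < 0.001")
        for _, row in hits.head(3).iterrows():
            print(f"  {row['set']}: p = {row['p']:.2e} (k={row['k']}/{row['K_set']})")


if __name__ == "__main__":
    main()
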