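"""Hypergeometric over-representation analysis against GMT gene sets.

For a query list of n genes drawn from a background universe of N genes,
the overlap k with a gene set of size K_set (after restriction to the
background) is scored by the upper-tail hypergeometric probability
P(X >= k); raw p-values are thresholded (default alpha = 0.001). The same
machinery annotates co-regulation modules with transcription-factor target
collections to produce a predicted-regulator table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .containers import DataError


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = "canonical"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, source: str = "canonical") -> GeneSetCollection:
    """Parse a tab-delimited GMT file (name, description, genes...).

    Duplicate genes within a set are removed (first occurrence kept).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: malformed GMT line {lineno} (needs name, description, >=1 gene)")
            name = parts[0]
            if name in sets:
                raise DataError(f"{path}: duplicate set name {name!r} at line {lineno}")
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise DataError(f"{path}: set {name!r} at line {lineno} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source, *genes]) + "\n")


def hypergeom_test(k: int, K_set: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K_set, n)."""
    if not (0 <= k <= min(K_set, n) <= N) or n > N or K_set > N:
        raise DataError(f"inconsistent hypergeometric counts k={k}, K={K_set}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K_set, n))


def enrich(
    query: list[str],
    collection: GeneSetCollection,
    background: list[str],
    alpha: float = 0.001,
) -> pd.DataFrame:
    """One record per gene set intersecting the background, sorted by p."""
    bg = set(background)
    q = set(query)
    dropped = q - bg
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes absent from background were dropped",
            stacklevel=2,
        )
        q &= bg
    N = len(bg)
    n = len(q)
    rows = []
    for name, genes in collection.sets.items():
        s = set(genes) & bg
        if not s:
            continue
        overlap = sorted(q & s)
        k = len(overlap)
        p = hypergeom_test(k, len(s), n, N)
        rows.append(
            {
                "set": name,
                "N": N,
                "K_set": len(s),
                "n": n,
                "k": k,
                "p": p,
                "significant": p < alpha,
                "overlap": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=["set", "N", "K_set", "n", "k", "p", "significant", "overlap"])
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def annotate_modules(
    modules: list[dict],
    tf_collection: GeneSetCollection,
    background: list[str],
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Predicted regulators: per module, TF-target sets at p < alpha."""
    rows = []
    for m in modules:
        genes = [g for g in m["genes"] if g in set(background)]
        if not genes:
            rows.append({"module": m["module"], "tf": None, "p": None, "k": 0})
            continue
        res = enrich(genes, tf_collection, background, alpha=alpha)
        hits = res[res["significant"]]
        if hits.empty:
            rows.append({"module": m["module"], "tf": None, "p": None, "k": 0})
        for _, h in hits.iterrows():
            rows.append({"module": m["module"], "tf": h["set"], "p": h["p"], "k": h["k"]})
    return pd.DataFrame(rows, columns=["module", "tf", "p", "k"])
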