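# scltmg

Single-cell transcriptomic characterization of a gene-knockdown contrast
(Ref-1/APE1 knockdown vs scrambled control, under hypoxia and normoxia),
implemented as a tested, reusable pipeline:

1. **Quality control** — cells with fewer than 250 or more than 10,000
   nonzero genes, or more than 15% mitochondrial counts, are excluded;
   genes detected in fewer than two retained cells are dropped.
2. **LTMG expression states and differential expression** — per gene, log
   expression follows a left-truncated mixture Gaussian: a K-component
   mixture (π_k, μ_k, σ_k) in which dropout zeros are left-censored at a
   cutoff Zcut. Censored cells contribute Σ_k π_k Φ((Zcut−μ_k)/σ_k) to the
   likelihood; observed cells contribute Σ_k π_k φ(x; μ_k, σ_k). Fitting
   is EM with closed-form censored moments, K chosen by BIC (3K−1
   parameters). Differential expression is a likelihood-ratio test,
   Λ = 2[ℓ_A + ℓ_B − ℓ_pooled] ~ χ²(3K−1), with Benjamini–Hochberg FDR
   control at 0.05.
3. **Co-regulation modules** — the per-gene expression-state matrix is
   binarized (consistently activated / suppressed) and factorized as a
   Boolean product U∘V by a greedy median-expansion heuristic (MEBF-style):
   rank-1 gene×cell patterns are extracted while their cover gain (new 1s
   covered minus 0s covered) stays positive. Module cells are tested for
   condition association (Fisher exact).
4. **Enrichment** — hypergeometric upper-tail test P(X ≥ k) of query gene
   lists and module gene sets against GMT collections (canonical pathways,
   TF targets), raw p < 0.001, background = detected genes.
5. **Metabolic flux surrogate** — per cell j, module fluxes over a
   metabolite–module stoichiometry S solve
   f_j = argmin_{f≥0} ‖S f‖² + λ‖f − a_j‖², where a_j is mean module-gene
   log expression (a deterministic convex stand-in for neural-network flux
   estimators); NADP⁺-consuming module fluxes are compared between groups
   by rank-sum tests.
6. **Proteomics cross-check** — per-protein Mann–Whitney comparison (exact
   permutation enumeration for combined n ≤ 12, tie-corrected normal
   approximation otherwise, raw p < 0.01) and RNA–protein sign-concordance.

A synthetic-data generator (`scltmg.synthetic`) emulates the study design —
two conditions × two oxygen states, 50 cells per group, censored-mixture
expression, planted DEGs, planted Boolean blocks, a 15-module NADP⁺ chain
graph with ground-truth fluxes, matched proteomics — and carries ground
truth for every downstream recovery test. Real count matrices (MTX/TSV)
can be ingested in place of the simulation.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic dataset (seed 1) and print what they find:

```
$ python analysis/01_simulate.py
wrote 2075 genes x 200 cells to results/sim
planted DEGs: 200  blocks: 3  flux modules: 15

$ python analysis/02_quality_control.py
retained 200/200 cells (excluded: none), 2075 genes detected

$ python analysis/03_differential_expression.py
105 upregulated and 368 downregulated genes at FDR < 0.05 (siRef1_hypoxia vs Scr_hypoxia)
planted-DEG recovery 199/200 (99.5%), direction accuracy 99.0%

$ python analysis/06_metabolic_flux.py
NADP+-consuming modules with Scr_hypoxia flux higher: 15/15
median rank-sum p across modules: 1.96e-09

$ python analysis/07_proteomics.py
320 upregulated and 594 downregulated proteins at p < 0.01 (siRef1_hypoxia vs Scr_hypoxia)
gene-protein pairs significant in both: 337; sign agreement 85.8% (overlap p = 2.93e-42)
```

Reading the numbers: 199 of the 200 planted differentially expressed genes
are recovered at FDR < 0.05 with the planted direction (the excess calls
beyond 200 are the test's finite-sample false positives, see
`docs/methods.md`); the flux comparison reproduces the designed pattern —
control cells carry higher NADP⁺-consuming flux in all 15 modules — and
the protein calls agree in sign with the RNA calls for the coupled
fraction of the proteome.

The same stages are available as CLI subcommands
(`scltmg simulate|qc|ltmg|deg|mebf|enrich|flux|dep|run|report`) and as one
orchestrated run from a JSON config (`scltmg run --config cfg.json`).

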