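# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices a maintainer would want to
know about.

## The censored-mixture expression model (LTMG)

Per gene, log-scale expression across cells is modeled as a K-component
Gaussian mixture left-censored at a cutoff Zcut (log-expression units):
an observed value x contributes the density Σ_k π_k φ(x; μ_k, σ_k), and a
dropout zero contributes the censored mass Σ_k π_k Φ((Zcut − μ_k)/σ_k).
The mixture components are interpreted as expression states: component 0
(lowest mean) is the suppressed/censored state, higher components are
active states. This treats dropout as a thresholding phenomenon on a
latent continuous expression level rather than as a separate
zero-inflation process — the key modeling assumption, which the synthetic
generator reproduces exactly.

**Fitting.** EM with closed-form censored moments: the E-step assigns
censored cells component weights ∝ π_k Φ(α_k) with α_k = (Zcut − μ_k)/σ_k,
and the M-step uses the truncated-normal conditional moments
E[X | X < Zcut] = μ − σλ(α) and Var[X | X < Zcut] = σ²(1 − αλ − λ²) with
λ = φ(α)/Φ(α). The objective (censored-data log-likelihood) is evaluated
every iteration and never decreases except when the σ floor clamps (then
flagged). Convergence: Δℓ < 1e-6 (tunable) or 500 iterations.

**Initialization** is deterministic: component k starts at the
(k + 0.5)/K quantile of the observed values; for K ≥ 2 two additional
offset-quantile starts (0.25, 0.75) are tried and the best final
likelihood wins. There is no random restart, so fits are reproducible
bit-for-bit.

**Model selection.** K ∈ {1..Kmax} (default 3) by BIC with 3K − 1 free
parameters. **σ floor**: 1e-2 log units — prevents degenerate spikes on
near-duplicate values; hitting it is flagged.

**Zcut.** Default is the per-gene minimum observed (nonzero) log value —
the tightest bound consistent with "zeros are censored". A global or
per-gene override exists: when the true detection limit is known (as it
is for simulated data), supplying it removes the small-sample
anti-conservativeness that bound estimation by the sample minimum induces
(see *Calibration*, below).

**An inner-loop detail.** The per-gene EM is compiled with numba when
available; an identical pure-numpy implementation is the reference path
and the two agree to ~1e-14 in log-likelihood (asserted in tests).

## Differential expression

For two condition groups A and B, each gene is tested by a likelihood
ratio: the pooled fit selects K by BIC; the A, B, and pooled likelihoods
are then maximized with that K fixed and Λ = 2[ℓ_A + ℓ_B − ℓ_pooled] is
referred to χ²(3K − 1). Benjamini–Hochberg controls the FDR over genes
(cutoff 0.05). The direction of a call is the sign of the difference in
π-weighted active-component means.

Optimization effort is deliberately symmetric: group fits are warm-started
from the pooled solution (EM monotonicity then guarantees Λ ≥ 0), the
pooled fit is re-optimized from the group solutions and their
size-weighted merge, and the group fits are refreshed from the final
pooled solution. Without this symmetry the statistic inherits an upward
bias from unequal optimizer quality.

**Calibration.** The χ² reference is asymptotic. Measured on 2,000+ null
genes from the generator's gene family at the study's 50 cells/group, the
empirical type-I error at p < 0.05 is ≈ 0.065–0.075 when the designed
censoring points are supplied, decaying to ≈ 0.05 by 200 cells/group; an
independent uncensored Gaussian-mixture LRT (sklearn EM) shows the same
finite-sample excess on identical data, so this is a property of the
statistic at this sample size, not of the implementation. Estimating Zcut
by the sample minimum adds roughly another 0.02–0.03 of type-I error at
this n. Practical consequence: at 50 cells/group, a few percent of null
genes reach FDR significance beyond the nominal rate, and those extra
calls carry essentially random directions.

## Boolean co-regulation modules

The state matrix is binarized two ways — *activated* (cell in the gene's
highest-mean component; genes with K = 1 have no activated state) and
*suppressed* (state 0) — and each binary matrix is factorized separately.

Rank-1 extraction is a median-expansion heuristic: seed with the column
whose nonzero count is the median among nonzero columns (ties to the
lower index); select all columns overlapping the seed on ≥ t of its ones
(t = 0.8 default); refine the row set against the selected columns;
iterate the refinement once more; run the symmetric row-seeded pass; keep
whichever candidate has the larger gain = (residual 1s covered) −
(residual 0s covered). Factorization accepts patterns while gain > 0 up
to a rank budget (default 10), zeroing covered ones in the residual.
Because the gain penalizes residual zeros (a superset of the original
matrix's zeros), accepted patterns always reduce the true reconstruction
error, which is recomputed from scratch as Hamming(M, U∘V).

On unstructured random 6×6 matrices the greedy gain reaches ≈ 0.7 of the
exhaustive rank-1 optimum on average (it never exceeds it); on matrices
that actually contain rank-1 structure it attains the optimum — the
heuristic is built for planted-block recovery, not adversarial noise.

Module–condition association is a Fisher exact 2×2 test of cell
membership vs condition (one-vs-rest per level when more than two levels
are present, strongest association reported).

## Enrichment

Upper-tail hypergeometric P(X ≥ k) via scipy's stable implementation,
verified against big-rational brute-force tail sums (exact to machine
precision on all instances with N ≤ 25 and sampled instances to N = 60).
Background defaults to the detected-gene universe; query genes outside
the background are dropped with a warning; raw p-values are thresholded
at 0.001 (no multiplicity correction by default, matching the practice of
thresholding printed raw enrichment p-values; BH is available on the DEG
side). TF-target collections run through the same machinery to produce a
predicted-regulator table per module.

## Flux surrogate

The estimator replaces a trained graph-neural-network flux model with a
deterministic convex program per cell:
f_j = argmin_{f≥0} ‖S f‖² + λ‖f − a_j‖², solved exactly by stacked
non-negative least squares (scipy NNLS). a_j is the mean log expression
of each module's genes, floored at 0; λ (default 1.0) trades metabolite
balance against expression anchoring — as λ → ∞, f → max(a, 0), and with
S = 0 that limit is exact at any λ. Modules with no matched genes are
excluded rather than imputed. Equivalence to the neural-network original
is explicitly not claimed; what is preserved is the input/output contract
(cells × modules non-negative fluxes from expression + stoichiometry) and
the qualitative group-comparison behavior.

## Proteomics

Per-protein two-sided Mann–Whitney: for combined n ≤ 12 the U null
distribution is enumerated over all C(n, n₁) assignments of pooled
midranks (a true permutation test, hence tie-safe; p = 2·min(tails)
capped at 1), otherwise scipy's tie-corrected normal approximation.
Constant proteins get p = 1. Direction is by median difference, so it is
invariant to monotone transforms. Concordance with the RNA side is the
sign-agreement fraction among gene–protein pairs significant in both
tables plus a hypergeometric overlap test on the mapped universe.

## Synthetic generator: what it emulates, and what it does not

The generator reproduces the study's design: two conditions × two oxygen
states (Scr/siRef1 × normoxia/hypoxia), 50 cells per group, 2,000 base
genes. Per gene, a two-component mixture (π_low ~ U(0.3, 0.5),
μ_low ~ U(0.5, 1.5), μ_high ~ U(3, 5), σ ~ U(0.4, 0.8)) is censored at
the point where the mixture CDF equals the dropout rate (0.3), so the
zero fraction matches in expectation; counts are round(exp(x)) floored at
1 for uncensored draws — zeros arise only via censoring, keeping the data
exactly inside the model family the fitter assumes. 10% of genes are
planted DEGs (half up, half down) with the active-component mean shifted
by ±2.0 log units in knockdown cells. Three 30-gene × 20-cell
co-activation blocks are planted by forcing the active component
(condition-biased cell sets; 5% of block entries flipped to the
suppressed component as noise). 5% of genes are flagged mitochondrial. A
15-module metabolite chain (all modules NADP⁺-consuming, 5 genes each)
drives module-gene expression as base + 1.2·flux + N(0, 0.3); per-cell
fluxes are a cell scale U(0.5, 2) times ±15% jitter, ×1.5 in control
cells — mirroring the expected "control higher in all 15 modules"
pattern. The proteomics matrix anchors each protein to its gene's
empirical group mean on the CPM log scale (the scale the DE test
analyzes) plus N(0, 0.3) noise, 6 replicates per group; a 20% decoupled
fraction has its group-mean vector permuted. All draws are seeded and
sub-generators use independent streams, so identical config + seed gives
byte-identical output.

Not emulated: read-level data, batch effects, doublets, cell-cycle
structure, ambient RNA, per-group capture variability (group sizes are
fixed), UMI saturation, and low-quality cells — every simulated cell
passes the QC filters by construction, so QC behavior is exercised by
dedicated fixtures rather than by the simulated study. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not robustness to the full messiness of real
single-cell data.

A note on composition: because planted effects act multiplicatively on
counts, large planted fractions or effect sizes shift total counts per
cell between groups and move every null gene on the CPM scale. At the
study conditions (10% planted, effect 2.0) this shift is small relative
to sampling noise; evaluations that need a clean null use balanced
draws.

## Problem sizes used in tests and acceptance

Chosen as the package's own evaluation design: oracle agreement on 100
uncensored genes (n = 1,000); parameter recovery on 100 genes × 2,000
draws from the identifiable censored family (Zcut = 0.5 — with censoring
at the 30% mixture quantile the low component can be 75–99% censored and
its location is information-theoretically unrecoverable, as the
truth-started direct MLE confirms); null calibration on 2,000–4,000 genes
at 50 cells/group with the designed censoring points; hypergeometric
exactness exhaustively for N ≤ 25 plus 500 sampled instances to N = 60;
Mann–Whitney enumeration for every group-size pair with combined n ≤ 12;
Boolean recovery on 30×24 (noise-free) and 40×30 (5% flips, overlapping
blocks) instances with an exhaustive 6×6 rank-1 oracle.

## Known limitations

- The LRT's χ² reference is anti-conservative by a few percent at
  50 cells/group (see *Calibration*); users comparing small groups should
  expect slightly more than nominal false positives, with random
  directions, and may prefer a permutation calibration for borderline
  calls.
- Zcut estimation by the sample minimum is biased upward; the override
  exists for platforms with a known detection limit.
- The greedy Boolean factorization is near-optimal only on structured
  matrices; rank selection is by the gain stopping rule, not a
  statistical model-order criterion.
- The flux surrogate shares only its interface with learned flux
  estimators; absolute flux scales are arbitrary units anchored to
  expression.
- Enrichment assumes a well-chosen background; the default
  (detected genes) is appropriate for DEG queries but module queries
  drawn from a pre-filtered universe should pass that universe
  explicitly.
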