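"""Generator correctness: determinism, censoring calibration, closed-form
truncated-mixture moments, graph structure, and the proteomics link."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from scltmg import synthetic as syn
from scltmg.containers import ConfigError


def test_identical_config_and_seed_reproduce_byte_identical_outputs(small_config):
    em1, t1 = syn.generate_counts(small_config)
    em2, t2 = syn.generate_counts(small_config)
    assert np.array_equal(em1.counts, em2.counts)
    assert list(em1.gene_ids) == list(em2.gene_ids)
    assert t1.deg_genes == t2.deg_genes
    pd.testing.assert_frame_equal(t1.true_flux, t2.true_flux)
    p1 = syn.generate_proteomics(t1, seed=3)
    p2 = syn.generate_proteomics(t2, seed=3)
    assert np.array_equal(p1.abundance, p2.abundance)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"frac_deg": 1.5},
        {"dropout_alpha": -0.1},
        {"n_genes": 0},
        {"n_cells_per_group": 0},
        {"noise_flip_rate": 2.0},
    ],
)
def test_invalid_configuration_raises(kwargs):
    with pytest.raises(ConfigError):
        syn.SyntheticConfig(**kwargs)


def test_censoring_fraction_matches_dropout_alpha():
    """The per-gene censoring point is calibrated so the zero fraction
    matches dropout_alpha in expectation (Monte-Carlo check at n=10,000)."""
    rng = np.random.default_rng(5)
    pi, mu, sigma = [0.4, 0.6], [1.0, 4.0], [0.5, 0.7]
    for alpha in (0.1, 0.3, 0.6):
        z = syn.censoring_point(pi, mu, sigma, alpha)
        _, cens = syn.sample_censored_mixture(rng, 10_000, pi, mu, sigma, z)
        assert cens.mean() == pytest.approx(alpha, abs=0.02)


def test_sample_mean_matches_closed_form_truncated_mixture_mean():
    """Mean of uncensored draws agrees with the analytic conditional mean
    E[X | X >= Zcut] of the mixture (independent closed-form oracle)."""
    rng = np.random.default_rng(6)
    pi, mu, sigma = np.array([0.4, 0.6]), np.array([1.0, 4.0]), np.array([0.5, 0.7])
    z = syn.censoring_point(pi, mu, sigma, 0.3)
    x, cens = syn.sample_censored_mixture(rng, 50_000, pi, mu, sigma, z)
    # independent re-derivation of the conditional mean via direct numerics
    grid = np.linspace(z, 12, 20_000)
    dens = pi[0] * norm.pdf(grid, mu[0], sigma[0]) + pi[1] * norm.pdf(grid, mu[1], sigma[1])
    oracle = np.trapezoid(grid * dens, grid) / np.trapezoid(dens, grid)
    assert oracle == pytest.approx(syn.truncated_mixture_mean(pi, mu, sigma, z), abs=1e-3)
    assert x[~cens].mean() == pytest.approx(oracle, abs=0.02)


def test_planted_effect_size_appears_in_generated_log_means():
    """Planted up-genes: the siRef1 active-component mean is shifted by
    +2.0; the difference in conditional means of nonzero log expression
    matches the closed-form difference under the generating mixture."""
    cfg = syn.SyntheticConfig(n_genes=2000, frac_deg=0.1, effect_size=2.0, seed=7,
                              n_modules=0, n_cells_per_group=50)
    em, truth = syn.generate_counts(cfg)
    up = [g for g, d in truth.deg_genes.items() if d == "up"]
    assert len(up) == 100
    gidx = {g: i for i, g in enumerate(em.gene_ids)}
    siref = np.array([c.startswith("siRef1") for c in em.cell_condition])
    diffs, oracle_diffs = [], []
    for g in up:
        p = truth.gene_mixture_params[g]
        pi, mu, s, z = p["pi"], np.array(p["mu"]), p["sigma"], p["zcut"]
        row = em.counts[gidx[g]]
        a = np.log(row[siref & (row > 0)]).mean() if (row[siref] > 0).any() else np.nan
        b = np.log(row[~siref & (row > 0)]).mean() if (row[~siref] > 0).any() else np.nan
        diffs.append(a - b)
        shifted = mu + np.array([0.0, 2.0])
        oracle_diffs.append(
            syn.truncated_mixture_mean(pi, shifted, s, z)
            - syn.truncated_mixture_mean(pi, mu, s, z)
        )
    # rounding to integer counts perturbs each gene slightly; averaged over
    # 100 genes the empirical shift must match the analytic one closely
    assert np.nanmean(diffs) == pytest.approx(np.mean(oracle_diffs), abs=0.1)
    assert np.mean(oracle_diffs) == pytest.approx(2.0, abs=0.5)


def test_zero_effect_size_produces_null_genes():
    cfg = syn.SyntheticConfig(n_genes=400, frac_deg=0.1, effect_size=0.0, seed=9,
                              n_modules=0, n_cells_per_group=40)
    em, truth = syn.generate_counts(cfg)
    assert truth.deg_genes  # directions recorded even with no effect
    siref = np.array([c.startswith("siRef1") for c in em.cell_condition])
    logc = np.log1p(em.counts)
    tstats = []
    for g in truth.deg_genes:
        i = list(em.gene_ids).index(g)
        a, b = logc[i, siref], logc[i, ~siref]
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        tstats.append((a.mean() - b.mean()) / se)
    assert abs(np.mean(tstats)) < 0.5


def test_truth_identifiers_exist_and_flux_nonnegative(small_dataset):
    em, truth = small_dataset
    ids = set(em.gene_ids)
    assert set(truth.deg_genes) <= ids
    for mod in truth.module_assignments:
        assert set(mod["genes"]) <= ids
        assert set(mod["cells"]) <= set(em.cell_ids)
    assert (truth.true_flux.to_numpy() >= 0).all()


# ---- module graph ---------------------------------------------------------


def test_graph_has_requested_module_count_and_nadp_flags():
    cfg = syn.SyntheticConfig(graph_spec=syn.GraphSpec(n_modules=15, n_metabolites=16))
    graph, flux = syn.generate_module_graph(cfg)
    assert len(graph.modules) == 15
    assert graph.nadp_consumer.sum() >= 1
    assert flux.shape[1] == 15


def test_degenerate_graph_spec_rejected():
    cfg = syn.SyntheticConfig()
    cfg.graph_spec = syn.GraphSpec(n_modules=0)
    with pytest.raises(ConfigError):
        syn.generate_module_graph(cfg)


def test_chain_conservation_interior_node_balanced():
    """On a chain A -> B -> C with equal fluxes, the interior metabolite
    has zero net production."""
    cfg = syn.SyntheticConfig(graph_spec=syn.GraphSpec(n_modules=2, n_metabolites=3))
    graph, _ = syn.generate_module_graph(cfg)
    imbalance = graph.S @ np.array([2.0, 2.0])
    assert imbalance[1] == 0.0  # interior node B


def test_flux_genes_scale_with_true_flux(small_dataset):
    em, truth = small_dataset
    logc = np.log1p(em.counts)
    gidx = {g: i for i, g in enumerate(em.gene_ids)}
    m = truth.graph.modules[0]
    activity = np.mean([logc[gidx[g]] for g in truth.graph.module_genes[m]], axis=0)
    f = truth.true_flux[m].to_numpy()
    from scipy.stats import spearmanr

    assert spearmanr(activity, f).statistic > 0.7


# ---- proteomics -----------------------------------------------------------


def test_fully_decoupled_proteomics_has_chance_level_sign_concordance(small_dataset):
    _, truth = small_dataset
    pm = syn.generate_proteomics(truth, n_replicates=6, decoupled_frac=1.0, seed=21)
    ggm = truth.gene_group_means
    agree = []
    for pid, gene in pm.protein_gene.items():
        i = list(pm.protein_ids).index(pid)
        a = pm.abundance[i, pm.sample_group == "siRef1_hypoxia"].mean()
        b = pm.abundance[i, pm.sample_group == "Scr_hypoxia"].mean()
        rna = ggm.loc[gene, "siRef1_hypoxia"] - ggm.loc[gene, "Scr_hypoxia"]
        if rna != 0 and a != b:
            agree.append((a > b) == (rna > 0))
    assert np.mean(agree) == pytest.approx(0.5, abs=0.12)


def test_noiseless_coupled_proteomics_preserves_difference_ranks(small_dataset):
    _, truth = small_dataset
    pm = syn.generate_proteomics(truth, n_replicates=3, noise_sd=0.0, decoupled_frac=0.0, seed=2)
    ggm = truth.gene_group_means
    a = pm.abundance[:, pm.sample_group == "siRef1_hypoxia"].mean(axis=1)
    b = pm.abundance[:, pm.sample_group == "Scr_hypoxia"].mean(axis=1)
    genes = [pm.protein_gene[p] for p in pm.protein_ids]
    rna = (ggm.loc[genes, "siRef1_hypoxia"] - ggm.loc[genes, "Scr_hypoxia"]).to_numpy()
    prot = a - b
    assert np.array_equal(np.argsort(np.argsort(prot)), np.argsort(np.argsort(rna)))


def test_too_few_replicates_rejected(small_dataset):
    _, truth = small_dataset
    with pytest.raises(ConfigError):
        syn.generate_proteomics(truth, n_replicates=1)
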