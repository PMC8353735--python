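"""LTMG censored-mixture fitting, state inference, and the LRT DE test.

Oracles: direct numerical maximization of the same censored likelihood
(scipy.optimize, independent code path), sklearn's uncensored Gaussian
mixture EM, hand-applied Benjamini-Hochberg, and statsmodels multipletests.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import norm

from scltmg import ltmg
from scltmg import synthetic as syn
from scltmg.containers import DataError

from conftest import make_matrix


# ---- log normalization ----------------------------------------------------


def test_log_normalize_closed_forms():
    counts = np.zeros((3, 1), dtype=int)
    counts[0, 0] = 1
    counts[1, 0] = 10**6 - 1
    m = make_matrix(counts)
    x, cens = ltmg.log_normalize(m)
    total = 10**6
    assert x[0, 0] == pytest.approx(np.log1p(1 * 1e6 / total))
    assert cens[2, 0] and x[2, 0] == 0.0
    # conservation: exp(x)-1 sums to the scale factor per cell
    assert (np.expm1(x).sum(axis=0) == pytest.approx(1e6))


def test_log_normalize_zero_total_cell_errors():
    m = make_matrix(np.zeros((3, 2), dtype=int))
    with pytest.raises(DataError):
        ltmg.log_normalize(m)


def test_log_normalize_conservation_on_fixture(small_dataset):
    em, _ = small_dataset
    x, _ = ltmg.log_normalize(em)
    assert np.allclose(np.expm1(x).sum(axis=0), 1e6)


# ---- fitting --------------------------------------------------------------


def test_constant_gene_fits_k1_at_sigma_floor():
    x = np.full(50, 2.5)
    fit = ltmg.fit_ltmg_gene(x, np.zeros(50, bool), kmax=3)
    assert fit.K == 1
    assert fit.mu[0] == pytest.approx(2.5, abs=1e-6)
    assert fit.sigma[0] == pytest.approx(ltmg.SIGMA_FLOOR)
    assert fit.pi[0] == pytest.approx(1.0)
    assert "sigma_floor" in fit.flags


def _neg_censored_loglik(theta, obs, n_cens, zcut):
    """Independent parameterization of the censored likelihood for the
    direct-optimizer oracle: theta = (logit pi_1, mu1, mu2, log s1, log s2)."""
    p1 = 1.0 / (1.0 + np.exp(-theta[0]))
    pi = np.array([p1, 1 - p1])
    mu = theta[1:3]
    sd = np.exp(theta[3:5])
    dens = pi[0] * norm.pdf(obs, mu[0], sd[0]) + pi[1] * norm.pdf(obs, mu[1], sd[1])
    ll = np.log(np.maximum(dens, 1e-300)).sum()
    if n_cens:
        mass = pi[0] * norm.cdf((zcut - mu[0]) / sd[0]) + pi[1] * norm.cdf((zcut - mu[1]) / sd[1])
        ll += n_cens * np.log(max(mass, 1e-300))
    return -ll


def test_parameter_recovery_matches_direct_numeric_mle():
    """2,000 censored draws from pi=(0.4,0.6), mu=(1,4), sigma=(0.5,0.7),
    Zcut=0.5: EM recovers mu within 0.15 and pi within 0.05, and its
    maximized likelihood matches an independent numerical optimizer."""
    rng = np.random.default_rng(42)
    x, cens = syn.sample_censored_mixture(rng, 2000, [0.4, 0.6], [1.0, 4.0], [0.5, 0.7], 0.5)
    fit = ltmg.fit_ltmg_gene(x, cens, zcut=0.5, K=2, tol=1e-9)
    assert np.abs(fit.mu - [1.0, 4.0]).max() < 0.15
    assert np.abs(fit.pi - [0.4, 0.6]).max() < 0.05

    obs = x[~cens]
    res = minimize(
        _neg_censored_loglik, x0=np.array([0.0, 0.5, 3.5, -0.5, -0.5]),
        args=(obs, int(cens.sum()), 0.5), method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10},
    )
    assert fit.loglik >= -res.fun - 1e-3  # EM at least as good as the oracle


def test_uncensored_fit_matches_sklearn_gmm():
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(3)
    x, _ = syn.sample_censored_mixture(rng, 1500, [0.35, 0.65], [0.5, 4.0], [0.6, 0.8], -np.inf)
    cens = np.zeros(x.size, bool)
    fit = ltmg.fit_ltmg_gene(x, cens, zcut=-np.inf, K=2, tol=1e-10, max_iter=3000)
    gm = GaussianMixture(2, n_init=5, tol=1e-10, max_iter=3000, random_state=0)
    gm.fit(x[:, None])
    oracle_ll = gm.score(x[:, None]) * x.size
    assert fit.loglik == pytest.approx(oracle_ll, abs=1e-4)


def test_compiled_and_numpy_em_paths_agree():
    """The numba inner loop and the reference numpy EM produce identical
    trajectories (same math, same starting point)."""
    from scltmg.ltmg import _em_fixed_k, _em_fixed_k_numpy, _quantile_init

    rng = np.random.default_rng(9)
    x, cens = syn.sample_censored_mixture(rng, 300, [0.4, 0.6], [1.0, 4.0], [0.5, 0.7], 0.5)
    obs = x[~cens]
    n_cens = int(cens.sum())
    for K in (1, 2, 3):
        pi0, mu0, s0 = _quantile_init(obs, n_cens, 0.5, K)
        a = _em_fixed_k(obs, n_cens, 0.5, pi0, mu0, s0, 1e-8, 500, 1e-2)
        b = _em_fixed_k_numpy(obs, n_cens, 0.5, pi0, mu0, s0, 1e-8, 500, 1e-2)
        assert a["loglik"] == pytest.approx(b["loglik"], abs=1e-9)
        assert np.allclose(a["mu"], b["mu"], atol=1e-9)
        assert np.allclose(a["pi"], b["pi"], atol=1e-9)


def test_em_loglik_monotone_no_flag():
    rng = np.random.default_rng(8)
    for seed in range(5):
        x, cens = syn.sample_censored_mixture(
            np.random.default_rng(seed), 300, [0.5, 0.5], [1.0, 3.5], [0.5, 0.5], 0.6
        )
        fit = ltmg.fit_ltmg_gene(x, cens, zcut=0.6, kmax=3)
        assert "nonmonotone" not in fit.flags


def test_bic_selects_k1_on_unimodal_and_k2_on_separated_bimodal():
    hits_k1, hits_k2 = 0, 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        uni = rng.normal(2.0, 0.6, size=400)
        f1 = ltmg.fit_ltmg_gene(uni, np.zeros(400, bool), zcut=uni.min(), kmax=3)
        hits_k1 += f1.K == 1
        bi, cens = syn.sample_censored_mixture(rng, 400, [0.5, 0.5], [1.0, 4.0], [0.5, 0.5], 0.3)
        f2 = ltmg.fit_ltmg_gene(bi, cens, zcut=0.3, kmax=3)
        hits_k2 += f2.K == 2
    assert hits_k1 >= 0.95 * n_seeds
    assert hits_k2 >= 0.95 * n_seeds


def test_mu_bias_shrinks_with_sample_size():
    biases = {}
    for n in (200, 2000):
        errs = []
        for seed in range(8):
            rng = np.random.default_rng(200 + seed)
            x, cens = syn.sample_censored_mixture(rng, n, [0.4, 0.6], [1.0, 4.0], [0.5, 0.7], 0.5)
            fit = ltmg.fit_ltmg_gene(x, cens, zcut=0.5, K=2)
            errs.append(np.abs(fit.mu - [1.0, 4.0]).max())
        biases[n] = np.mean(errs)
    assert biases[2000] < biases[200]


def test_all_censored_gene_degenerate_flagged():
    x = np.zeros(30)
    fit = ltmg.fit_ltmg_gene(x, np.ones(30, bool), zcut=0.5)
    assert fit.K == 1
    assert "degenerate_all_censored" in fit.flags


def test_too_few_observations_rejected():
    with pytest.raises(DataError):
        ltmg.fit_ltmg_gene(np.ones(5), np.zeros(5, bool))


# ---- state inference ------------------------------------------------------


def test_censored_state_assignment_follows_censored_mass():
    """K=2, mu=(0,5), sigma=(1,1), pi=(0.5,0.5), Zcut=0: the censored mass
    Phi(0) = 0.5 vs Phi(-5) ~ 3e-7, so censored cells get state 0."""
    fit = ltmg.LTMGFit(
        K=2, pi=np.array([0.5, 0.5]), mu=np.array([0.0, 5.0]),
        sigma=np.array([1.0, 1.0]), zcut=0.0, loglik=0.0, bic=0.0,
        n_iter=1, converged=True,
    )
    expected = int(np.argmax([np.log(0.5) + log_ndtr(0.0), np.log(0.5) + log_ndtr(-5.0)]))
    s = ltmg.infer_states(fit, np.array([0.0, 4.9]), np.array([True, False]))
    assert s[0] == expected == 0
    assert s[1] == 1


def test_posterior_crossover_tie_breaks_to_lower_mean_component():
    fit = ltmg.LTMGFit(
        K=2, pi=np.array([0.5, 0.5]), mu=np.array([1.0, 3.0]),
        sigma=np.array([1.0, 1.0]), zcut=-10.0, loglik=0.0, bic=0.0,
        n_iter=1, converged=True,
    )
    # x=2.0 is exactly equidistant: identical densities -> state 0
    s = ltmg.infer_states(fit, np.array([2.0]), np.array([False]))
    assert s[0] == 0


def test_k1_fit_gives_all_state_zero():
    x = np.full(20, 1.5)
    fit = ltmg.fit_ltmg_gene(x, np.zeros(20, bool), kmax=1)
    assert (ltmg.infer_states(fit, x, np.zeros(20, bool)) == 0).all()


# ---- BH FDR ---------------------------------------------------------------


def test_bh_hand_examples():
    assert np.allclose(ltmg.bh_fdr(np.array([1.0, 1.0, 1.0])), 1.0)
    q = ltmg.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(q, 0.04)
    assert ltmg.bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)


def test_bh_matches_statsmodels_and_dominates_p():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    p = rng.uniform(size=200) ** 2
    q = ltmg.bh_fdr(p)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, q_sm)
    assert (q >= p - 1e-15).all()


def test_bh_propagates_nan():
    q = ltmg.bh_fdr(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(q[1]) and not np.isnan(q[0])


# ---- DE test --------------------------------------------------------------


def test_identical_groups_give_zero_statistic():
    rng = np.random.default_rng(12)
    x, cens = syn.sample_censored_mixture(rng, 40, [0.4, 0.6], [1.0, 4.0], [0.5, 0.7], 0.5)
    logmat = np.vstack([np.concatenate([x, x])])
    censm = np.vstack([np.concatenate([cens, cens])])
    groups = np.array(["A"] * 40 + ["B"] * 40)
    out = ltmg.deg_test(logmat, censm, groups)
    assert out.loc[0, "lrt_stat"] == pytest.approx(0.0, abs=1e-3)
    assert out.loc[0, "p_value"] == pytest.approx(1.0, abs=1e-3)


def test_null_statistic_nonnegative_and_roughly_calibrated():
    """200-gene null: Lambda >= 0 always and the p<0.05 rate is near 5%
    (the full 2,000-gene calibration lives in the acceptance suite)."""
    rng = np.random.default_rng(77)
    n_genes, n = 200, 100
    logmat = np.empty((n_genes, n))
    censm = np.empty((n_genes, n), bool)
    for i in range(n_genes):
        logmat[i], censm[i] = syn.sample_censored_mixture(
            rng, n, [0.4, 0.6], [1.0, 4.0], [0.5, 0.7], 0.5
        )
    groups = np.array(["A", "B"] * (n // 2))
    out = ltmg.deg_test(logmat, censm, groups)
    assert (out["lrt_stat"].dropna() >= 0).all()
    rate = (out["p_value"] < 0.05).mean()
    assert 0.0 <= rate <= 0.12


def test_planted_degs_recovered_with_correct_direction(small_config):
    em, truth = syn.generate_counts(small_config)
    logmat, cens = ltmg.log_normalize(em)
    mask = np.isin(em.cell_condition, ["siRef1_hypoxia", "Scr_hypoxia"])
    out = ltmg.deg_test(
        logmat[:, mask], cens[:, mask], em.cell_condition[mask],
        group_order=("siRef1_hypoxia", "Scr_hypoxia"),
    )
    out["gene"] = em.gene_ids
    sig = out[out["q_value"] < 0.05]
    planted = set(truth.deg_genes)
    recovered = planted & set(sig["gene"])
    assert len(recovered) / len(planted) >= 0.5  # small-n spot check
    dirs = sig.set_index("gene")["direction"]
    correct = [dirs[g] == truth.deg_genes[g] for g in recovered]
    assert np.mean(correct) >= 0.9


def test_gene_fully_censored_in_one_group_is_na():
    rng = np.random.default_rng(5)
    x, cens = syn.sample_censored_mixture(rng, 20, [0.5, 0.5], [1, 4], [0.5, 0.5], 0.5)
    row = np.concatenate([x, np.zeros(20)])
    crow = np.concatenate([cens, np.ones(20, bool)])
    out = ltmg.deg_test(np.vstack([row]), np.vstack([crow]), np.array(["A"] * 20 + ["B"] * 20))
    assert np.isnan(out.loc[0, "p_value"])
    assert out.loc[0, "direction"] == "NA"
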