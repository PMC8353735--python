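"""Compiled inner loop for the censored-mixture EM.

Numerically identical to the numpy reference implementation in
:mod:`scltmg.ltmg` (which remains the fallback when numba is absent); the
compiled path exists because the differential-expression test refits every
gene several times and the per-iteration work is tiny.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _log_ndtr(a: float) -> float:
    if a > -25.0:
        return math.log(0.5 * math.erfc(-a / _SQRT2))
    return -0.5 * a * a - math.log(-a) - _LOG_SQRT_2PI


@njit(cache=True)
def _loglik(obs, n_cens, zcut, pi, mu, sigma):
    K = pi.shape[0]
    ll = 0.0
    tmp = np.empty(K)
    for i in range(obs.shape[0]):
        mx = -1e308
        for k in range(K):
            z = (obs[i] - mu[k]) / sigma[k]
            tmp[k] = math.log(pi[k]) - 0.5 * z * z - math.log(sigma[k]) - _LOG_SQRT_2PI
            if tmp[k] > mx:
                mx = tmp[k]
        s = 0.0
        for k in range(K):
            s += math.exp(tmp[k] - mx)
        ll += mx + math.log(s)
    if n_cens > 0:
        mx = -1e308
        for k in range(K):
            tmp[k] = math.log(pi[k]) + _log_ndtr((zcut - mu[k]) / sigma[k])
            if tmp[k] > mx:
                mx = tmp[k]
        s = 0.0
        for k in range(K):
            s += math.exp(tmp[k] - mx)
        ll += n_cens * (mx + math.log(s))
    return ll


@njit(cache=True)
def em_fixed_k(obs, n_cens, zcut, pi0, mu0, sigma0, tol, max_iter, sigma_floor):
    """Censored-mixture EM from one starting point.

    Returns (pi, mu, sigma, loglik, n_iter, converged, nonmonotone, floored).
    """
    K = pi0.shape[0]
    n_obs = obs.shape[0]
    pi = pi0.copy()
    mu = mu0.copy()
    sigma = np.maximum(sigma0.copy(), sigma_floor)
    gamma = np.empty((n_obs, K))
    lp = np.empty(K)
    w = np.zeros(K)
    m_c = np.zeros(K)
    v_c = np.zeros(K)
    ll = _loglik(obs, n_cens, zcut, pi, mu, sigma)
    nonmono = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: observed responsibilities
        for i in range(n_obs):
            mx = -1e308
            for k in range(K):
                z = (obs[i] - mu[k]) / sigma[k]
                lp[k] = math.log(pi[k]) - 0.5 * z * z - math.log(sigma[k])
                if lp[k] > mx:
                    mx = lp[k]
            s = 0.0
            for k in range(K):
                gamma[i, k] = math.exp(lp[k] - mx)
                s += gamma[i, k]
            for k in range(K):
                gamma[i, k] /= s
        # E-step: censored weights and conditional moments
        if n_cens > 0:
            mx = -1e308
            for k in range(K):
                lp[k] = math.log(pi[k]) + _log_ndtr((zcut - mu[k]) / sigma[k])
                if lp[k] > mx:
                    mx = lp[k]
            s = 0.0
            for k in range(K):
                w[k] = math.exp(lp[k] - mx)
                s += w[k]
            for k in range(K):
                w[k] /= s
                alpha = (zcut - mu[k]) / sigma[k]
                lphi = -0.5 * alpha * alpha - _LOG_SQRT_2PI
                lam = math.exp(lphi - _log_ndtr(alpha))
                m_c[k] = mu[k] - sigma[k] * lam
                vv = sigma[k] * sigma[k] * (1.0 - alpha * lam - lam * lam)
                v_c[k] = vv if vv > 0.0 else 0.0
        # M-step
        for k in range(K):
            nk = n_cens * w[k]
            sx = n_cens * w[k] * m_c[k]
            for i in range(n_obs):
                nk += gamma[i, k]
                sx += gamma[i, k] * obs[i]
            if nk < 1e-12:
                nk = 1e-12
            mu_new = sx / nk
            ss = n_cens * w[k] * (v_c[k] + (m_c[k] - mu_new) * (m_c[k] - mu_new))
            for i in range(n_obs):
                d = obs[i] - mu_new
                ss += gamma[i, k] * d * d
            var = ss / nk
            if var < sigma_floor * sigma_floor:
                var = sigma_floor * sigma_floor
            mu[k] = mu_new
            sigma[k] = math.sqrt(var)
            pi[k] = nk
        s = 0.0
        for k in range(K):
            s += pi[k]
        for k in range(K):
            pi[k] /= s

        prev = ll
        ll = _loglik(obs, n_cens, zcut, pi, mu, sigma)
        if ll < prev - 1e-6 * (1.0 + abs(prev)):
            nonmono = True
        if abs(ll - prev) < tol:
            converged = True
            break

    floored = False
    for k in range(K):
        if sigma[k] <= sigma_floor * 1.0000001:
            floored = True
    order = np.argsort(mu)
    return pi[order], mu[order], sigma[order], ll, it, converged, nonmono, floored
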