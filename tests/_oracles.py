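"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's recursive implementations: HMM
likelihoods are computed by exhaustive enumeration of state paths with
scipy densities, and the state-space smoother is checked against a direct
joint-Gaussian conditional built by explicit matrix algebra.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.special import logsumexp


def wc_logpdf(theta, lam, kappa):
    return np.log(
        (1.0 - kappa**2) / (2.0 * np.pi * (1.0 + kappa**2 - 2.0 * kappa * np.cos(theta - lam)))
    )


def emission_logdens(speeds, turns, gammas, wcs):
    """(T, 2) log emission densities with scipy's gamma pdf; NaN turns
    contribute the speed term only."""
    T = len(speeds)
    ld = np.zeros((T, 2))
    for s in range(2):
        mu, sigma = gammas[s]
        shape = mu**2 / sigma**2
        scale = sigma**2 / mu
        ld[:, s] = stats.gamma.logpdf(speeds, a=shape, scale=scale)
        lam, kappa = wcs[s]
        ok = np.isfinite(turns)
        ld[ok, s] += wc_logpdf(turns[ok], lam, kappa)
    return ld


def exhaustive_loglik(speeds, turns, gammas, wcs, tm, delta):
    """Log-likelihood by summing over all 2^T state paths."""
    ld = emission_logdens(np.asarray(speeds, float), np.asarray(turns, float), gammas, wcs)
    T = ld.shape[0]
    terms = []
    for path in itertools.product((0, 1), repeat=T):
        lp = np.log(delta[path[0]]) + ld[0, path[0]]
        for t in range(1, T):
            lp += np.log(tm[path[t - 1], path[t]]) + ld[t, path[t]]
        terms.append(lp)
    return logsumexp(terms)


def exhaustive_viterbi(speeds, turns, gammas, wcs, tm, delta):
    """Most probable state path by full enumeration."""
    ld = emission_logdens(np.asarray(speeds, float), np.asarray(turns, float), gammas, wcs)
    T = ld.shape[0]
    best, best_lp = None, -np.inf
    for path in itertools.product((0, 1), repeat=T):
        lp = np.log(delta[path[0]]) + ld[0, path[0]]
        for t in range(1, T):
            lp += np.log(tm[path[t - 1], path[t]]) + ld[t, path[t]]
        if lp > best_lp:
            best, best_lp = path, lp
    return np.asarray(best), best_lp


def dcrw_joint_gaussian_smoother(grid_times, obs_times, obs_vals, obs_var, gamma_c, sigma2, prior_var):
    """Smoothed node means/variances for a 1-D DCRW by direct conditioning.

    Nodes x_0..x_K. Prior: x_0, x_1 iid N(first obs value, prior_var);
    x_k = x_{k-1} + gamma_c (x_{k-1} - x_{k-2}) + eta. Observations tie to
    nodes by linear interpolation weights. Returns (mean, var) at each node.
    """
    K = len(grid_times) - 1
    n = K + 1
    # build x = m0 + L e with e standard normal (innovations representation)
    L = np.zeros((n, n))
    m0 = np.full(n, obs_vals[0])
    L[0, 0] = np.sqrt(prior_var)
    L[1, 1] = np.sqrt(prior_var)
    for k in range(2, n):
        # x_k = (1+g) x_{k-1} - g x_{k-2} + sqrt(sigma2) e_k
        L[k] = (1 + gamma_c) * L[k - 1] - gamma_c * L[k - 2]
        L[k, k] += np.sqrt(sigma2)
        m0[k] = (1 + gamma_c) * m0[k - 1] - gamma_c * m0[k - 2]
    P = L @ L.T
    # observation matrix
    W = np.zeros((len(obs_times), n))
    step = grid_times[1] - grid_times[0]
    for i, tau in enumerate(obs_times):
        k = min(max(int(np.ceil((tau - grid_times[0]) / step)), 1), K)
        w = (tau - grid_times[k - 1]) / step
        W[i, k] = w
        W[i, k - 1] = 1 - w
    S = W @ P @ W.T + np.diag(obs_var)
    G = P @ W.T @ np.linalg.inv(S)
    mean = m0 + G @ (obs_vals - W @ m0)
    cov = P - G @ W @ P
    return mean, np.diag(cov)
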