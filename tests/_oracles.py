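"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the marginal
likelihood is integrated by dense Gauss-Hermite quadrature instead of a
Laplace approximation, the MANOVA null distribution is enumerated by
exhaustive permutation, and filter counts are recomputed by a naive
per-variant loop.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln


def quad_loglik(panel, beta, Sigma, random_slopes, n_nodes=60):
    """Marginal binomial GLMM log-likelihood by tensor Gauss-Hermite quadrature."""
    diets = list(dict.fromkeys(panel["diet"]))
    strains = list(dict.fromkeys(panel["strain"]))
    k = len(diets) if random_slopes else 1
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    L = np.linalg.cholesky(Sigma)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.meshgrid(*([x] * k), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    wts = np.prod(
        np.stack(np.meshgrid(*([w] * k), indexing="ij"), axis=0).reshape(k, -1), axis=0
    )
    b = np.sqrt(2.0) * pts @ L.T
    beta = np.asarray(beta, dtype=float)
    offs = np.concatenate([[0.0], beta[1:]])
    total = 0.0
    for s in strains:
        sub = panel[panel["strain"] == s]
        ll = np.zeros(len(b))
        for _, r in sub.iterrows():
            j = diets.index(r["diet"])
            eta = beta[0] + offs[j] + b[:, 0]
            if random_slopes and j > 0:
                eta = eta + b[:, j]
            y, n = float(r["n_pupated"]), float(r["n_seeded"])
            ll += (
                y * eta
                - n * np.logaddexp(0.0, eta)
                + gammaln(n + 1)
                - gammaln(y + 1)
                - gammaln(n - y + 1)
            )
        m = ll.max()
        total += m + np.log(np.sum(wts * np.exp(ll - m))) - (k / 2.0) * np.log(np.pi)
    return float(total)


def pillai_trace_V(Y, X_full, X_reduced):
    """Pillai's trace statistic (not p-value) from two nested fits."""

    def sscp(X):
        bhat, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ bhat
        return R.T @ R

    E = sscp(X_full)
    H = sscp(X_reduced) - E
    return float(np.trace(H @ np.linalg.inv(H + E)))


def exact_permutation_manova_p(Y, genotype, covariate=None):
    """Exact permutation p for a two-group MANOVA by full enumeration.

    Enumerates every assignment of the observed group sizes to lines and
    compares Pillai's trace of each to the observed one.
    """
    Y = np.asarray(Y, dtype=float)
    n = len(Y)
    g = np.asarray(genotype, dtype=float)
    n_alt = int(g.sum())
    cols_red = [np.ones(n)]
    if covariate is not None:
        cols_red.append(np.asarray(covariate, dtype=float))
    X_red = np.column_stack(cols_red)
    V_obs = pillai_trace_V(Y, np.column_stack(cols_red[:1] + [g] + cols_red[1:]), X_red)
    count = total = 0
    for idx in itertools.combinations(range(n), n_alt):
        gp = np.zeros(n)
        gp[list(idx)] = 1.0
        X_full = np.column_stack(cols_red[:1] + [gp] + cols_red[1:])
        V = pillai_trace_V(Y, X_full, X_red)
        count += V >= V_obs - 1e-12
        total += 1
    return count / total


def brute_force_filter_count(calls, min_per_group=5):
    """Naive per-variant count of survivors of the allele-count filter."""
    kept = 0
    for row in calls:
        obs = row[row >= 0]
        if (obs == 0).sum() >= min_per_group and (obs == 1).sum() >= min_per_group:
            kept += 1
    return kept
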