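"""Numba kernel for the confidence-weighted Bayesian elastic-net Gibbs sampler.

The model for one protein is y = X beta + eps, eps_i ~ N(0, sigma2 / w_i),
where w_i blends identification confidence with a robustness kernel on the
standardized residual. The elastic-net prior is written in Gaussian
scale-mixture form, with penalties adapted per coefficient block (peptide,
treatment, donor, and the two interaction blocks) because the blocks live on
very different scales — ionization effects span log2 units while most
interactions are null. The L1 component is the adaptive Bayesian lasso: each
coefficient carries its own lam1_j^2 with a Gamma hyperprior, so clearly
supported effects escape shrinkage while null coefficients stay heavily
shrunk; the ridge component lam2 adapts per block:

  beta_j | sigma2, tau_j, lam2_b ~ N(0, sigma2 / (1/tau_j + lam2_b)),
  tau_j ~ Exp(lam1_j^2 / 2),  lam1_j^2 ~ Gamma(a1, b1),  lam2_b ~ Gamma(a2, b2).

Column 0 (the intercept) is unpenalized (fixed prior precision 1e-8).
Blocks listed in ``ridge_only`` drop the L1 component (1/tau_j = 0): the
peptide-by-treatment and peptide-by-donor interactions are not sparse in
sum-to-zero coordinates (a one-peptide occupancy shift makes every
coefficient of the block nonzero), so an L1 prior there would bias occupancy
contrasts toward zero. Blocks with ``lam2_fixed[b] > 0`` keep that ridge
value instead of adapting it: the peptide-by-treatment block holds the
reported occupancy effect sizes, and an adaptive ridge would shrink the few
large (modified-peptide) coefficients toward the block's many small ones.

Conditionals:
  beta     | . ~ N(A^-1 b, sigma2 A^-1),  A = X'WX + D, b = X'Wy, D = diag(d_j)
  sigma2   | . ~ InvGamma(a0 + (n + p_pen)/2, b0 + (SSR_w + sum d_j beta_j^2)/2)
  1/tau_j  | . ~ InvGauss(sqrt(lam1_j^2 sigma2 / beta_j^2), lam1_j^2)
  lam1_j^2 | . ~ Gamma(a1 + 1, b1 + tau_j / 2)
  lam2_b   | . ~ Gamma(a2 + p_b/2, b2 + sum_b beta_j^2 / (2 sigma2))
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INTERCEPT_PREC = 1e-8


@njit(cache=True)
def _invgauss(mu, lam):
    # Michael-Schucany-Haas transform
    nu = np.random.normal() ** 2
    x = mu + mu * mu * nu / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * nu + mu * mu * nu * nu
    )
    if x <= 1e-12:
        x = 1e-12
    if np.random.uniform(0.0, 1.0) <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _chol_solve(L, b):
    # solve L L' x = b
    p = b.shape[0]
    y = np.empty(p)
    for i in range(p):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    x = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = y[i]
        for k in range(i + 1, p):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _upper_backsolve(L, z):
    # solve L' x = z (L lower triangular)
    p = z.shape[0]
    x = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = z[i]
        for k in range(i + 1, p):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def gibbs_elastic_net(
    X,
    y,
    qc,
    block,
    n_blocks,
    ridge_only,
    lam2_fixed,
    n_iter,
    burn_in,
    c,
    use_weights,
    a1,
    b1,
    a2,
    b2,
    fix_lambda,
    lam1_sq_init,
    lam2_init,
    seed,
):
    """Run the sampler; returns post-burn-in draws, Rao-Blackwell conditional
    means, sigma2 draws, and the mean observation weights.

    ``block[j]`` gives the penalty block of column j (-1 = unpenalized
    intercept); each block carries its own lam1^2 and lam2.
    """
    np.random.seed(seed)
    n, p = X.shape
    n_save = n_iter - burn_in
    Xt = X.T.copy()

    beta_draws = np.empty((n_save, p))
    beta_cond_means = np.empty((n_save, p))
    sigma2_draws = np.empty(n_save)
    weight_sum = np.zeros(n)

    block_size = np.zeros(n_blocks)
    for j in range(p):
        if block[j] >= 0:
            block_size[block[j]] += 1.0

    # initialization: ridge solve with unit penalty
    A0 = np.dot(Xt, X)
    for j in range(p):
        A0[j, j] += 1.0
    L0 = np.linalg.cholesky(A0)
    beta = _chol_solve(L0, np.dot(Xt, y))
    r = y - np.dot(X, beta)
    sigma2 = (r @ r) / max(n, 1) + 1e-6

    # the lam1 -> 0 limit is pure ridge: drop the scale mixture entirely to
    # avoid heavy-tailed tau jitter around a degenerate mixing distribution
    l1_collapsed = fix_lambda and lam1_sq_init < 1e-8
    tau_inv = np.ones(p)
    for j in range(p):
        if block[j] >= 0 and (ridge_only[block[j]] or l1_collapsed):
            tau_inv[j] = 0.0
    lam1_sq = np.full(p, lam1_sq_init)
    lam2 = np.full(n_blocks, lam2_init)
    if not fix_lambda:
        for b in range(n_blocks):
            if lam2_fixed[b] > 0.0:
                lam2[b] = lam2_fixed[b]
    d = np.empty(p)
    for j in range(p):
        d[j] = _INTERCEPT_PREC if block[j] < 0 else tau_inv[j] + lam2[block[j]]
    p_pen = 0
    for j in range(p):
        if block[j] >= 0:
            p_pen += 1
    a0 = 1e-3
    b0 = 1e-3

    w = np.ones(n)
    wy = np.empty(n)
    for it in range(n_iter):
        # observation weights from current standardized residuals
        if use_weights:
            r = y - np.dot(X, beta)
            csd = c * np.sqrt(sigma2)
            for i in range(n):
                ri = r[i] / csd
                w[i] = qc[i] + (1.0 - qc[i]) / (1.0 + ri * ri)
        # beta | rest
        Xw = X * w.reshape(n, 1)
        A = np.dot(Xt, Xw)
        for j in range(p):
            A[j, j] += d[j]
        for i in range(n):
            wy[i] = w[i] * y[i]
        bvec = np.dot(Xt, wy)
        L = np.linalg.cholesky(A)
        m = _chol_solve(L, bvec)
        z = np.empty(p)
        for j in range(p):
            z[j] = np.random.normal()
        beta = m + np.sqrt(sigma2) * _upper_backsolve(L, z)

        # sigma2 | rest
        r = y - np.dot(X, beta)
        ssr = 0.0
        for i in range(n):
            ssr += w[i] * r[i] * r[i]
        pen = 0.0
        for j in range(p):
            pen += d[j] * beta[j] * beta[j]
        shape = a0 + 0.5 * (n + p_pen)
        rate = b0 + 0.5 * (ssr + pen)
        sigma2 = rate / np.random.gamma(shape, 1.0)
        if sigma2 < 1e-12:
            sigma2 = 1e-12

        # tau_inv | rest
        for j in range(p):
            if block[j] < 0 or ridge_only[block[j]] or l1_collapsed:
                continue
            bj2 = beta[j] * beta[j]
            if bj2 < 1e-12:
                bj2 = 1e-12
            mu = np.sqrt(lam1_sq[j] * sigma2 / bj2)
            if mu > 1e6:
                mu = 1e6
            tau_inv[j] = _invgauss(mu, lam1_sq[j])

        if not fix_lambda:
            for j in range(p):
                if block[j] >= 0 and not ridge_only[block[j]]:
                    lam1_sq[j] = np.random.gamma(a1 + 1.0, 1.0 / (b1 + 0.5 / tau_inv[j]))
            for b in range(n_blocks):
                if block_size[b] == 0 or lam2_fixed[b] > 0.0:
                    continue
                bsum = 0.0
                for j in range(p):
                    if block[j] == b:
                        bsum += beta[j] * beta[j]
                lam2[b] = np.random.gamma(
                    a2 + 0.5 * block_size[b], 1.0 / (b2 + 0.5 * bsum / sigma2)
                )

        for j in range(p):
            if block[j] >= 0:
                d[j] = tau_inv[j] + lam2[block[j]]

        if it >= burn_in:
            k = it - burn_in
            beta_draws[k] = beta
            beta_cond_means[k] = m
            sigma2_draws[k] = sigma2
            weight_sum += w

    return beta_draws, beta_cond_means, sigma2_draws, weight_sum / n_save
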