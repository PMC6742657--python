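"""Shared statistical primitives: BH adjustment, variance moderation, MCMC diagnostics.

The Benjamini-Hochberg step-up is implemented directly from its definition
(q_(i) = min_{j>=i} p_(j) * n / j, clipped at 1) so that adjusted values agree
with the textbook formula to the last bit; variance moderation follows the
classical moderated-t derivation (moment matching of log sample variances
against a scaled inverse-chi-square prior).
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    Parameters
    ----------
    pvalues : array of p-values in [0, 1].

    Returns
    -------
    Array of the same shape with step-up adjusted values; monotone
    non-decreasing in ranked p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    np.minimum(q_sorted, 1.0, out=q_sorted)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from per-unit sample
    variances ``s2`` with residual degrees of freedom ``df``.

    Assumes s2 ~ s0^2 * F(df, d0); moment-matches mean and variance of
    log(s2) using digamma/trigamma identities. Returns (d0, s0_2); d0 may be
    ``inf`` when the variances are essentially exchangeable with no excess
    spread.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2 or np.unique(s2).size < 2:
        return 0.0, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return float(d0), s0_2


def moderated_variance(s2: np.ndarray, df: np.ndarray, d0: float, s0_2: float) -> np.ndarray:
    """Posterior (shrunken) variance s_tilde^2 = (d0*s0^2 + df*s2)/(d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_2)
    if d0 == 0:
        return s2.copy()
    return (d0 * s0_2 + df * s2) / (d0 + df)


def split_rhat(chain: np.ndarray) -> float:
    """Split-R-hat of a single chain (split into two halves)."""
    x = np.asarray(chain, dtype=float)
    m = x.size // 2
    if m < 2:
        return np.nan
    halves = np.stack([x[:m], x[m : 2 * m]])
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean()
    b = m * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (m - 1) / m * w + b / m
    return float(np.sqrt(var_plus / w))


def batch_mcse(chain: np.ndarray, n_batches: int = 30) -> float:
    """Monte-Carlo standard error of the chain mean via batch means."""
    x = np.asarray(chain, dtype=float)
    nb = min(n_batches, max(2, x.size // 4))
    size = x.size // nb
    if size < 1:
        return float(np.std(x, ddof=1) / np.sqrt(max(x.size, 1)))
    means = x[: nb * size].reshape(nb, size).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(nb))
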