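"""Independent reference implementations used to cross-check the
package.  Each oracle is deliberately coded from the defining formula
(or by brute force) rather than sharing any code path with milkomics.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def svd_pls(X, Y, n_components):
    """PLS by per-component SVD of the cross-covariance.

    For each component the weight is the leading left singular vector of
    X'Y on the deflated X; scores/loadings follow and X is deflated.
    Returns (W, T, P) arrays.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xr = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if Yc.ndim == 1:
        Yc = Yc[:, None]
    p = X.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((X.shape[0], n_components))
    P = np.zeros((p, n_components))
    for a in range(n_components):
        U, s, Vt = np.linalg.svd(Xr.T @ Yc, full_matrices=False)
        w = U[:, 0]
        t = Xr @ w
        pv = Xr.T @ t / (t @ t)
        W[:, a], T[:, a], P[:, a] = w, t, pv
        Xr = Xr - np.outer(t, pv)
    return W, T, P


def vip_brute_force(W, ssy):
    """VIP_j from its definition, loop-coded."""
    W = np.asarray(W, dtype=float)
    ssy = np.asarray(ssy, dtype=float)
    p, A = W.shape
    out = np.zeros(p)
    denom = ssy.sum()
    for j in range(p):
        acc = 0.0
        for a in range(A):
            wa = W[:, a]
            acc += ssy[a] * (wa[j] / np.linalg.norm(wa)) ** 2
        out[j] = np.sqrt(p * acc / denom)
    return out


def bh_brute_force(p_values):
    """BH q-values from the min-over-tail definition:
    q_i = min_{j: p_j >= p_i} (m * p_j / rank_j), computed per element."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(m * ranked[j] / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def mann_whitney_exact_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    ranks to the first group (no ties assumed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1  # no ties: plain ranks
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    all_ranks = np.arange(1, n1 + n2 + 1)
    for combo in combinations(range(n1 + n2), n1):
        r = all_ranks[list(combo)].sum()
        u = r - n1 * (n1 + 1) / 2
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def ols_normal_equations(y, X_design):
    """OLS coefficients, standard errors and two-sided t-test p-values
    straight from the normal equations."""
    from scipy import stats

    X = np.asarray(X_design, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(XtX_inv) * s2)
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, pvals


def quartiles_by_sorting(values):
    """Median/P25/P75 with linear interpolation, coded from the type-7
    definition (independent of numpy.percentile)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    out = []
    for q in (0.5, 0.25, 0.75):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        out.append(v[lo] + (h - lo) * (v[hi] - v[lo]))
    return tuple(out)  # (median, p25, p75)
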