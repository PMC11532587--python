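"""Internal vectorized regression kernels.

Replicate-level simulation suites (type-I-error calibration, coverage, bootstrap
confidence intervals) refit linear and logistic models thousands of times; the
generic model APIs in statsmodels carry per-fit overhead that dominates at that
scale.  These kernels implement exactly the textbook estimators — OLS with
classical standard errors and logistic IRLS (Newton–Raphson on the canonical
link) — on raw ndarrays.  Tests assert agreement with statsmodels to near
machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "ols_fit",
    "logistic_fit",
    "per_snp_linear",
    "per_snp_logistic",
]


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of ``y`` on design ``X`` (including any intercept column).

    Returns (coef, se, resid).  Classical (homoskedastic) standard errors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    xtx = X.T @ X
    xty = X.T @ y
    coef = np.linalg.solve(xtx, xty)
    resid = y - X @ coef
    dof = n - k
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    return coef, se, resid


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic regression by Newton–Raphson.  Returns (coef, se, converged).

    ``beta0`` warm-starts the iteration (useful in bootstrap loops where the
    resample optimum is near the full-sample one).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        beta = np.zeros(k)
        # start the intercept (assumed first all-ones column if present) at
        # the empirical log-odds to cut iterations on rare outcomes
        ybar = y.mean()
        if 0.0 < ybar < 1.0 and np.all(X[:, 0] == 1.0):
            beta[0] = np.log(ybar / (1.0 - ybar))
    converged = False
    xtwx = np.empty((k, k))

    def loglik(b):
        eta = X @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        np.einsum("ij,i,il->jl", X, w, X, out=xtwx)
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError as exc:  # separation / collinearity
            raise RuntimeError(f"logistic fit failed: singular information ({exc})")
        # step-halving: Newton can overshoot on rare outcomes
        for _ in range(25):
            ll_new = loglik(beta + step)
            if ll_new >= ll - 1e-12:
                break
            step = 0.5 * step
        beta = beta + step
        ll = ll_new
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    p = special.expit(eta)
    w = p * (1.0 - p)
    np.einsum("ij,i,il->jl", X, w, X, out=xtwx)
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30:
        raise RuntimeError(
            "logistic fit diverged (possible separation); max |coef| "
            f"{np.max(np.abs(beta)):.2f}"
        )
    return beta, se, converged

def per_snp_linear(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simple linear regression of ``y`` on each column of ``G`` (with intercept).

    Vectorized across columns.  Returns (beta, se, pval) arrays of length M.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    gbar = G.mean(axis=0)
    ybar = y.mean()
    gc = G - gbar
    yc = y - ybar
    sgg = np.einsum("ij,ij->j", gc, gc)
    sgy = yc @ gc
    beta = sgy / sgg
    # residual variance per SNP from the identity RSS = Syy - beta * Sgy
    syy = float(yc @ yc)
    rss = syy - beta * sgy
    dof = n - 2
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / sgg)
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    return beta, se, pval


def per_snp_logistic(
    G: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Logistic regression of binary ``y`` on each column of ``G`` separately.

    Each per-SNP model has two parameters (intercept, slope); all M Newton
    updates are carried simultaneously with closed-form 2x2 solves.
    Returns (beta, se, pval) for the slope terms.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    a = np.full(m, special.logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        p = special.expit(eta)
        r = y[:, None] - p
        w = p * (1.0 - p)
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", G, r)
        s0 = w.sum(axis=0)
        s1 = np.einsum("ij,ij->j", G, w)
        s2 = np.einsum("ij,ij,ij->j", G, G, w)
        det = s0 * s2 - s1 * s1
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    eta = a[None, :] + G * b[None, :]
    p = special.expit(eta)
    w = p * (1.0 - p)
    s0 = w.sum(axis=0)
    s1 = np.einsum("ij,ij->j", G, w)
    s2 = np.einsum("ij,ij,ij->j", G, G, w)
    det = s0 * s2 - s1 * s1
    se = np.sqrt(s0 / det)
    z = b / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return b, se, pval
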