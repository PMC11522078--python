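"""Random-intercept linear mixed models with Satterthwaite degrees of freedom.

The model is y = X beta + Z b + e with one random intercept per group
(participant): b ~ N(0, sigma_b^2), e ~ N(0, sigma^2).  Because the random
structure is a single intercept, the likelihood profiles down to a
one-dimensional search over the variance ratio lambda = sigma_b^2/sigma^2:
for fixed lambda each group's covariance is I + lambda J, whose inverse and
determinant are closed-form, so one profiled-deviance evaluation costs
O(N p^2).  This makes the mass-univariate (per-timepoint) fits of the
timecourse analysis cheap enough for the crossvalidation and null-calibration
simulations.

Satterthwaite df follow the usual recipe: for the j-th coefficient,
df = 2 g^2 / (grad g' W grad g), where g(theta) = Var(beta_j | theta) and W
is the asymptotic covariance of the variance components theta =
(sigma_b^2, sigma^2) taken from the observed information of the profiled
(over beta) log-likelihood.  A normal-approximation p-value is always
exposed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOGLAM_BOUNDS = (-15.0, 15.0)


@dataclass
class _Precomp:
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    S: np.ndarray      # (G, p) per-group sums of X rows
    t: np.ndarray      # (G,) per-group sums of y
    n_g: np.ndarray    # (G,) group sizes
    n: int
    p: int


def _precompute(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> _Precomp:
    _, inv = np.unique(groups, return_inverse=True)
    G = inv.max() + 1
    p = X.shape[1]
    S = np.zeros((G, p))
    np.add.at(S, inv, X)
    t = np.bincount(inv, weights=y, minlength=G)
    n_g = np.bincount(inv, minlength=G).astype(float)
    return _Precomp(X.T @ X, X.T @ y, float(y @ y), S, t, n_g, len(y), p)


def _gls(pre: _Precomp, lam: float):
    """GLS quantities at variance ratio lam: (beta, A, rss_v, logdet_v)."""
    w = lam / (1.0 + lam * pre.n_g)                      # (G,)
    A = pre.XtX - (pre.S * w[:, None]).T @ pre.S
    c = pre.Xty - pre.S.T @ (w * pre.t)
    q = pre.yty - float(w @ (pre.t**2))
    beta = np.linalg.solve(A, c)
    rss_v = q - float(beta @ c)
    logdet_v = float(np.sum(np.log1p(lam * pre.n_g)))
    return beta, A, rss_v, logdet_v


def _ml_deviance(pre: _Precomp, lam: float) -> float:
    _, _, rss, logdet = _gls(pre, lam)
    sigma2 = max(rss / pre.n, 1e-300)
    return pre.n * np.log(2 * np.pi * sigma2) + logdet + pre.n


def _reml_deviance(pre: _Precomp, lam: float) -> float:
    _, A, rss, logdet = _gls(pre, lam)
    nm = pre.n - pre.p
    sigma2 = max(rss / nm, 1e-300)
    sign, logdet_a = np.linalg.slogdet(A)
    return nm * np.log(2 * np.pi * sigma2) + logdet + logdet_a + nm


@dataclass
class MixedLMResult:
    """Fitted random-intercept model; t tests use Satterthwaite df."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    df: np.ndarray                 # Satterthwaite, fractional
    pvalues: np.ndarray            # from t on Satterthwaite df
    pvalues_normal: np.ndarray     # normal-approximation fallback
    sigma2: float
    sigma2_group: float
    loglik: float
    n: int
    n_groups: int
    reml: bool
    df_method: str                 # "satterthwaite" or "residual-fallback"

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "df": self.df,
                "p": self.pvalues,
                "p_normal": self.pvalues_normal,
            },
            index=self.names,
        )


def _neg2ll_theta(
    pre: _Precomp, sigma2_b: float, sigma2: float, reml: bool = False
) -> float:
    """Profiled-over-beta -2 log-(restricted-)likelihood at theta."""
    lam = sigma2_b / sigma2
    _, A, rss, logdet = _gls(pre, lam)
    if reml:
        _, logdet_a = np.linalg.slogdet(A)
        return (
            (pre.n - pre.p) * np.log(2 * np.pi * sigma2)
            + logdet + logdet_a + rss / sigma2
        )
    return pre.n * np.log(2 * np.pi * sigma2) + logdet + rss / sigma2


def _satterthwaite(
    pre: _Precomp, sigma2_b: float, sigma2: float, reml: bool = False
) -> np.ndarray | None:
    """Per-coefficient Satterthwaite df; None when the information matrix
    is unusable (e.g. boundary fits)."""
    theta = np.array([sigma2_b, sigma2])
    h = np.maximum(1e-4 * np.abs(theta), 1e-8)

    def var_beta(th):
        lam = max(th[0], 0.0) / th[1]
        _, A, _, _ = _gls(pre, lam)
        return th[1] * np.diag(np.linalg.inv(A))

    g0 = var_beta(theta)
    # gradient of each coefficient's variance wrt theta (central differences)
    grad = np.zeros((pre.p, 2))
    for i in range(2):
        lo = theta.copy(); lo[i] -= h[i]
        hi = theta.copy(); hi[i] += h[i]
        if lo[i] < 0:
            lo[i] = 0.0
        grad[:, i] = (var_beta(hi) - var_beta(lo)) / (hi[i] - lo[i])

    # observed information of theta from the profiled -2ll (halved)
    def d2(i, j):
        e_i = np.zeros(2); e_i[i] = h[i]
        e_j = np.zeros(2); e_j[j] = h[j]
        f = lambda th: _neg2ll_theta(pre, max(th[0], 1e-12), max(th[1], 1e-12), reml)
        return (
            f(theta + e_i + e_j) - f(theta + e_i - e_j)
            - f(theta - e_i + e_j) + f(theta - e_i - e_j)
        ) / (4 * h[i] * h[j])

    H = np.array([[d2(0, 0), d2(0, 1)], [d2(0, 1), d2(1, 1)]])
    try:
        W = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    denom = np.einsum("pi,ij,pj->p", grad, W, grad)
    if np.any(~np.isfinite(denom)) or np.any(denom <= 0):
        return None
    df = 2.0 * g0**2 / denom
    if np.any(~np.isfinite(df)) or np.any(df <= 0):
        return None
    return np.maximum(df, 1.0)


def fit_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    reml: bool = False,
) -> MixedLMResult:
    """Fit y = X beta + (1 | group) + e by ML (default) or REML.

    X must include the intercept column.  Raises np.linalg.LinAlgError on a
    singular fixed-effects design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) matching y")
    pre = _precompute(X, y, np.asarray(groups))
    dev = _reml_deviance if reml else _ml_deviance

    res = optimize.minimize_scalar(
        lambda u: dev(pre, np.exp(u)), bounds=_LOGLAM_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    if dev(pre, 0.0) <= res.fun:      # boundary: no group variance
        lam = 0.0

    beta, A, rss, _ = _gls(pre, lam)
    denom = pre.n - pre.p if reml else pre.n
    sigma2 = rss / denom
    sigma2_b = lam * sigma2
    cov_beta = sigma2 * np.linalg.inv(A)
    bse = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / bse, 0.0)

    df = None
    if lam > 1e-10:
        df = _satterthwaite(pre, sigma2_b, sigma2, reml)
    if df is None:
        df = np.full(pre.p, float(pre.n - pre.p))
        df_method = "residual-fallback"
    else:
        df_method = "satterthwaite"

    p_t = 2 * stats.t.sf(np.abs(tvals), df)
    p_z = 2 * stats.norm.sf(np.abs(tvals))
    loglik = -0.5 * _ml_deviance(pre, lam) if not reml else -0.5 * dev(pre, lam)
    return MixedLMResult(
        names=names or [f"x{j}" for j in range(pre.p)],
        params=beta, bse=bse, tvalues=tvals, df=df,
        pvalues=p_t, pvalues_normal=p_z,
        sigma2=float(sigma2), sigma2_group=float(sigma2_b),
        loglik=float(loglik), n=pre.n, n_groups=len(pre.n_g),
        reml=reml, df_method=df_method,
    )
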