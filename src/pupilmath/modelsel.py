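"""Best-subset regression with BIC model selection and BIC-approximate
Bayes factors, for predicting anxiety questionnaire scores from task
performance and pupil features.

Conventions
-----------
The outcome (a questionnaire total) is z-scored before modelling with the
n-1 sample standard deviation; predictors are left on their native scales.
All candidate models are ordinary Gaussian regressions fit by least
squares.  BIC uses the maximum-likelihood error variance (SSE/n) and
counts the intercept, the slope coefficients, and the error variance as
parameters:

    BIC = -2 log L_max + k ln(n),   k = #predictors + 2

Under this convention the intercept-only model on any z-scored outcome of
length n has a BIC that depends only on n (206.14 at n = 70).  Differences
in BIC approximate twice the log Bayes factor under a unit-information
prior, so BF(A over B) = exp((BIC_B - BIC_A) / 2).

Out-of-sample skill is summarised by leave-one-subject-out cv-R^2 =
1 - SSE_loo / SST; negative values are floored at 0 for reporting (a model
that predicts worse than the mean has no predictive value), with the raw
value also returned.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical predictor columns of the per-participant feature table
FEATURE_COLUMNS = ("accuracy", "pmp", "baseline_ps", "max_dilation", "peak_latency")


def zscore(x: np.ndarray) -> np.ndarray:
    """z-score with the n-1 (sample) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass
class SubsetModelFit:
    """One candidate regression over a subset of predictors."""

    predictors: tuple[str, ...]
    coef: np.ndarray           # intercept first
    sse: float
    r2: float
    adj_r2: float
    bic: float
    loglik: float
    n: int

    @property
    def k(self) -> int:
        """Parameter count: intercept + slopes + error variance."""
        return len(self.predictors) + 2


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("collinear predictors: rank %d < %d columns", rank, X.shape[1])
    resid = y - X @ coef
    return coef, float(resid @ resid)


def gaussian_loglik(sse: float, n: int) -> float:
    """Maximised Gaussian log-likelihood with MLE variance SSE/n."""
    sigma2 = max(sse / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def fit_subset(
    table: pd.DataFrame, outcome: np.ndarray, predictors: tuple[str, ...]
) -> SubsetModelFit:
    """Least-squares fit of `outcome ~ 1 + predictors` with BIC bookkeeping."""
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    X = np.column_stack(
        [np.ones(n)] + [table[p].to_numpy(dtype=float) for p in predictors]
    )
    coef, sse = _ols(X, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    p = len(predictors)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    ll = gaussian_loglik(sse, n)
    bic = -2.0 * ll + (p + 2) * np.log(n)
    return SubsetModelFit(predictors, coef, sse, r2, adj, bic, ll, n)


def null_bic(outcome: np.ndarray) -> float:
    """BIC of the intercept-only model on a z-scored outcome.

    The outcome must already be z-scored with the n-1 standard deviation;
    the value then depends only on n (206.14 for n = 70).
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sse = float(np.sum((y - y.mean()) ** 2))
    return -2.0 * gaussian_loglik(sse, n) + 2.0 * np.log(n)


def bayes_factor(bic_a: float, bic_b: float) -> float:
    """Bayes factor favouring model A over model B from their BICs."""
    if not (np.isfinite(bic_a) and np.isfinite(bic_b)):
        raise ValueError("BICs must be finite")
    return float(np.exp((bic_b - bic_a) / 2.0))


def best_subset(
    table: pd.DataFrame,
    outcome: np.ndarray,
    predictors: tuple[str, ...] = FEATURE_COLUMNS,
) -> list[SubsetModelFit]:
    """Fit all 2^p predictor subsets (including the null model); return them
    sorted by BIC, best first."""
    if len(predictors) > 15:
        raise ValueError("exhaustive search capped at 15 predictors")
    fits = [
        fit_subset(table, outcome, subset)
        for r in range(len(predictors) + 1)
        for subset in itertools.combinations(predictors, r)
    ]
    return sorted(fits, key=lambda f: f.bic)


def loo_cv(
    table: pd.DataFrame, outcome: np.ndarray, predictors: tuple[str, ...]
) -> tuple[float, float]:
    """Leave-one-subject-out cv-R^2 for one predictor subset.

    Returns (floored, raw): the raw value is 1 - SSE_loo/SST with SST about
    the full-sample mean; the floored value clips negatives to 0.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 participants")
    X = np.column_stack(
        [np.ones(n)] + [table[p].to_numpy(dtype=float) for p in predictors]
    )
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        coef, _ = _ols(X[train], y[train])
        preds[i] = X[i] @ coef
    sse = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    raw = 1.0 - sse / sst
    return max(raw, 0.0), raw


def adj_r2_from_f(f_stat: float, u: int, v: int) -> tuple[float, float]:
    """(R^2, adjusted R^2) implied by an F statistic with (u, v) df."""
    if f_stat < 0 or u < 1 or v < 1:
        raise ValueError("need F >= 0 and u, v >= 1")
    r2 = u * f_stat / (u * f_stat + v)
    adj = 1.0 - (1.0 - r2) * (u + v) / v
    return r2, adj


@dataclass
class ComparisonReport:
    """Ranked best-subset results for one outcome, Table-2 style."""

    outcome: str
    fits: list[SubsetModelFit]
    table: pd.DataFrame = field(repr=False)

    @property
    def best(self) -> SubsetModelFit:
        return self.fits[0]

    def bf_matrix(self, top: int = 10) -> pd.DataFrame:
        names = [" + ".join(f.predictors) or "(null)" for f in self.fits[:top]]
        bics = [f.bic for f in self.fits[:top]]
        m = np.exp((np.subtract.outer(bics, bics)).T / 2.0)
        return pd.DataFrame(m, index=names, columns=names)


def rank_models(
    table: pd.DataFrame,
    outcome_column: str,
    predictors: tuple[str, ...] = FEATURE_COLUMNS,
    with_loo: bool = True,
) -> ComparisonReport:
    """Full best-subset analysis of one questionnaire outcome.

    The outcome column is z-scored; every predictor subset is fit and
    ranked by BIC; each fit gains `bf_vs_null` and (optionally) `cv_r2` /
    `cv_r2_raw` attributes, and a summary DataFrame mirrors the ranked list.
    """
    y = zscore(table[outcome_column].to_numpy(dtype=float))
    fits = best_subset(table, y, predictors)
    bic0 = null_bic(y)
    rows = []
    for f in fits:
        f.bf_vs_null = bayes_factor(f.bic, bic0)  # type: ignore[attr-defined]
        if with_loo:
            f.cv_r2, f.cv_r2_raw = loo_cv(table, y, f.predictors)  # type: ignore[attr-defined]
        rows.append(
            {
                "model": " + ".join(f.predictors) or "(null)",
                "n_predictors": len(f.predictors),
                "r2": f.r2,
                "adj_r2": f.adj_r2,
                "bic": f.bic,
                "bf_vs_null": f.bf_vs_null,
                **({"cv_r2": f.cv_r2} if with_loo else {}),
            }
        )
    return ComparisonReport(outcome_column, fits, pd.DataFrame(rows))


def power_curve(
    n_grid: np.ndarray,
    partial_r2: float,
    u: int = 1,
    alpha: float = 0.05,
    convention: str = "cohen",
) -> pd.DataFrame:
    """Power of the F test of u regression coefficients across sample sizes.

    The effect size is Cohen's f^2 = partial_r2 / (1 - partial_r2); the
    noncentrality is lambda = f^2 (u + v + 1) under the "cohen" convention
    or lambda = f^2 n under "total-n", with v = n - u - 1 denominator df.
    """
    if not 0 < partial_r2 < 1:
        raise ValueError("partial_r2 must lie in (0, 1)")
    if convention not in ("cohen", "total-n"):
        raise ValueError("convention must be 'cohen' or 'total-n'")
    f2 = partial_r2 / (1.0 - partial_r2)
    rows = []
    for n in np.asarray(n_grid, dtype=int):
        v = n - u - 1
        if v < 1:
            rows.append({"n": int(n), "v": v, "power": np.nan})
            continue
        lam = f2 * (u + v + 1) if convention == "cohen" else f2 * n
        fcrit = stats.f.isf(alpha, u, v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            power = float(stats.ncf.sf(fcrit, u, v, lam))
        rows.append({"n": int(n), "v": v, "power": power})
    out = pd.DataFrame(rows)
    out.attrs.update(partial_r2=partial_r2, u=u, alpha=alpha, convention=convention)
    return out


def required_n(
    partial_r2: float,
    u: int = 1,
    alpha: float = 0.05,
    target_power: float = 0.80,
    n_max: int = 1000,
    convention: str = "cohen",
) -> int:
    """Smallest n on the power curve reaching `target_power`."""
    grid = np.arange(u + 3, n_max + 1)
    curve = power_curve(grid, partial_r2, u, alpha, convention)
    ok = curve[curve["power"] >= target_power]
    if ok.empty:
        raise ValueError(f"power {target_power} not reached by n = {n_max}")
    return int(ok["n"].iloc[0])
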