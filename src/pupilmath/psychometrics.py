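"""Descriptive statistics and auxiliary analyses of the questionnaire
battery: Pearson correlations with Fisher-z confidence intervals, paired
difficulty contrasts, Cronbach's alpha, and k-means clustering of math
anxiety against task accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    ci_low: float
    ci_high: float

    @property
    def df(self) -> int:
        return self.n - 2


def pearson_ci(x, y, conf: float = 0.95) -> CorrelationResult:
    """Pearson correlation with two-sided p and a Fisher-z confidence interval.

    CI = tanh(atanh(r) +/- z_crit / sqrt(n - 3)); p from the exact t
    transform t = r sqrt(n-2) / sqrt(1-r^2) on n-2 df.  Perfect correlations
    return the degenerate interval [r, r].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        return CorrelationResult(r, n, 0.0, r, r)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), n - 2)
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    half = zcrit / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
    return CorrelationResult(r, n, float(p), float(lo), float(hi))


def paired_t(a, b) -> tuple[float, int, float]:
    """Classical paired t test; returns (t, df, p) with df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two paired vectors of length >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, len(a) - 1, 1.0
        raise ValueError("zero variance of differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an (n respondents x k items) matrix:
    alpha = k/(k-1) * (1 - sum item variances / variance of total)."""
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 respondents")
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of the total score")
    item_var = items.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    centers: np.ndarray          # in standardized feature space
    centers_raw: np.ndarray      # back on the original scales
    inertia: float
    feature_names: tuple[str, ...]
    seed: int


def cluster_ma_accuracy(
    table: pd.DataFrame,
    features: tuple[str, ...] = ("amas", "accuracy"),
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterSolution:
    """Best-of-restarts k-means on standardized features (default: math
    anxiety score vs task accuracy), as used to expose the high-MA /
    low-accuracy subgroup."""
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError("fewer participants than clusters")
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(Xs)
    centers_raw = scaler.inverse_transform(km.cluster_centers_)
    return ClusterSolution(
        k, labels, km.cluster_centers_, centers_raw, float(km.inertia_), features, seed
    )


def median_split(values) -> np.ndarray:
    """High/low labels by median split (plotting convenience only)."""
    v = np.asarray(values, dtype=float)
    return np.where(v > np.median(v), "high", "low")


def describe_battery(
    table: pd.DataFrame,
    columns: tuple[str, ...] | None = None,
    item_tables: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Descriptives table: mean, median, sd, min, max, skew, excess kurtosis,
    and Cronbach's alpha where item-level responses are supplied.

    Skew and kurtosis are the bias-uncorrected moment estimators; kurtosis
    is excess (normal = 0).
    """
    columns = columns or tuple(table.select_dtypes("number").columns)
    rows = []
    for c in columns:
        v = table[c].to_numpy(dtype=float)
        rows.append(
            {
                "measure": c,
                "mean": v.mean(),
                "median": float(np.median(v)),
                "sd": v.std(ddof=1),
                "min": v.min(),
                "max": v.max(),
                "skew": float(stats.skew(v, bias=True)),
                "kurtosis": float(stats.kurtosis(v, fisher=True, bias=True)),
                "cronbach_alpha": (
                    cronbach_alpha(item_tables[c]) if item_tables and c in item_tables else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame, columns: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations with significance markers
    (*** p<.001, ** p<.01, * p<.05, . p<.1)."""
    columns = columns or tuple(table.select_dtypes("number").columns)
    out = pd.DataFrame(index=columns, columns=columns, dtype=object)
    for i, a in enumerate(columns):
        for j, b in enumerate(columns):
            if i == j:
                out.loc[a, b] = "1"
                continue
            res = pearson_ci(table[a], table[b])
            stars = (
                "***" if res.p < 0.001 else "**" if res.p < 0.01
                else "*" if res.p < 0.05 else "." if res.p < 0.1 else ""
            )
            out.loc[a, b] = f"{res.r:.2f}{stars}"
    return out
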