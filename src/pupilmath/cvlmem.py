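"""Crossvalidated timepoint selection with linear mixed models.

Testing whether a covariate (difficulty cue, anxiety score, accuracy, or
their interactions) modulates the pupil timecourse faces a multiple-
comparisons problem across timepoints.  The procedure here sidesteps it by
crossvalidation: each participant's trials are split deterministically into
3 folds; two folds serve as the training set on which a random-intercept
mixed model is fit at every timepoint, and the timepoint with the peak
|t| statistic for each fixed effect is selected; the left-out fold's trials
then contribute their pupil value at that timepoint.  After rotating the
test fold three times, every trial carries exactly one selected pupil value
per effect, and a final random-intercept model over all trials yields the
reported t, df, and p.  Because selection never sees the test fold, the
final test is valid at nominal alpha.

Two complements are provided: a consensus-cluster scan (maximal runs of
timepoints where all rotations show |t| > 2, optionally confirmed by a
mixed model on the within-window mean), and a deliberately liberal
per-timepoint scan with no multiplicity correction, used to bound how much
an effect could have been missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import MixedLMResult, fit_random_intercept

T_CONSENSUS = 2.0
N_FOLDS = 3


# ---------------------------------------------------------------- codings

def expand_terms(spec: str | list[str]) -> list[str]:
    """Expand a compact effect spec: 'cue*amas + accuracy' ->
    ['cue', 'amas', 'cue:amas', 'accuracy']."""
    if isinstance(spec, str):
        parts = [p.strip() for p in spec.split("+")]
    else:
        parts = list(spec)
    terms: list[str] = []
    for p in parts:
        if "*" in p:
            factors = [f.strip() for f in p.split("*")]
            for f in factors:
                if f not in terms:
                    terms.append(f)
            inter = ":".join(factors)
            if inter not in terms:
                terms.append(inter)
        elif p and p not in terms:
            terms.append(p)
    return terms


def code_covariates(trials: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Return coded covariate columns for the model terms.

    Cue is sum-coded (-0.5 easy, +0.5 hard); binary 0/1 columns (trial
    accuracy) are centered; other continuous covariates are z-scored.
    Interactions are products of coded main effects.
    """
    coded = pd.DataFrame(index=trials.index)
    mains = {t for t in terms if ":" not in t}
    mains |= {f for t in terms for f in t.split(":")}
    for name in mains:
        col = trials[name]
        if col.dtype == object or str(col.dtype) == "category":
            vals = col.map({"easy": -0.5, "hard": 0.5})
            if vals.isna().any():
                raise ValueError(f"unknown levels in categorical term {name!r}")
            coded[name] = vals.astype(float)
        else:
            v = col.to_numpy(dtype=float)
            uniq = np.unique(v)
            if set(uniq) <= {0.0, 1.0}:
                coded[name] = v - v.mean()
            else:
                sd = v.std(ddof=1)
                if sd == 0:
                    raise ValueError(f"constant covariate {name!r}")
                coded[name] = (v - v.mean()) / sd
    for t in terms:
        if ":" in t:
            prod = np.ones(len(trials))
            for f in t.split(":"):
                prod = prod * coded[f].to_numpy()
            coded[t] = prod
    return coded[terms]


def build_design(coded: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(coded))] + [coded[c].to_numpy() for c in coded])
    return X, ["intercept", *coded.columns]


# ------------------------------------------------------------------ folds

def assign_folds(trials: pd.DataFrame, n_folds: int = N_FOLDS) -> pd.Series:
    """Deterministic fold assignment: within each participant, trials ranked
    by trial index get fold = rank mod n_folds + 1 (folds as even as the
    trial count allows)."""
    rank = trials.groupby("participant")["trial"].rank(method="first").astype(int) - 1
    return (rank % n_folds + 1).rename("fold")


# ------------------------------------------------------- per-timepoint fit

def fit_timepoint_model(
    data: pd.DataFrame,
    coded: pd.DataFrame,
    outcome: str = "pupil",
    reml: bool = False,
) -> MixedLMResult | None:
    """Random-intercept model of one timepoint's pupil values on the coded
    covariates.  Returns None on a singular fit."""
    X, names = build_design(coded.loc[data.index])
    try:
        return fit_random_intercept(
            X, data[outcome].to_numpy(dtype=float),
            data["participant"].to_numpy(), names=names, reml=reml,
        )
    except np.linalg.LinAlgError:
        return None


@dataclass
class TimepointStats:
    """t statistics per (rotation, timepoint, effect), training folds only."""

    timepoints: np.ndarray
    effects: list[str]
    t: np.ndarray          # (n_rotations, n_timepoints, n_effects); NaN = singular
    df: np.ndarray
    estimate: np.ndarray


@dataclass
class ConsensusCluster:
    effect: str
    t_start: float
    t_end: float
    min_abs_t: float       # over rotations and timepoints in the interval
    window_fit: MixedLMResult | None = None


@dataclass
class CvLmemResult:
    effects: list[str]
    selected_timepoints: dict[str, dict[int, float]]   # effect -> rotation -> time
    final_fits: dict[str, MixedLMResult]
    stats: TimepointStats
    clusters: list[ConsensusCluster] = field(default_factory=list)

    def effect_test(self, effect: str) -> tuple[float, float, float]:
        """(t, df, p) of one effect in its final crossvalidated model."""
        fit = self.final_fits[effect]
        j = fit.names.index(effect)
        return fit.tvalues[j], fit.df[j], fit.pvalues[j]


def _pivot(long: pd.DataFrame, outcome: str = "pupil"):
    """Wide trial x timepoint matrix plus the per-trial covariate frame."""
    key = ["participant", "trial"]
    wide = long.pivot_table(index=key, columns="time", values=outcome, aggfunc="first")
    trial_info = long.drop_duplicates(key).set_index(key).drop(
        columns=[c for c in ("time", outcome) if c in long], errors="ignore"
    )
    trial_info = trial_info.loc[wide.index]
    return wide, trial_info


def crossvalidated_effect_test(
    long: pd.DataFrame,
    effect_spec: str | list[str],
    n_folds: int = N_FOLDS,
    consensus_threshold: float = T_CONSENSUS,
    reml: bool = False,
    fit_cluster_models: bool = True,
) -> CvLmemResult:
    """The full crossvalidated timepoint-selection procedure.

    `long` is the analysis table with columns participant, trial, time,
    pupil, and the covariates named in `effect_spec`.  Timepoints must lie
    on a grid shared across trials (trials may be missing at late
    timepoints; they simply drop from those fits).
    """
    terms = expand_terms(effect_spec)
    wide, trial_info = _pivot(long)
    timepoints = wide.columns.to_numpy(dtype=float)
    coded = code_covariates(trial_info.reset_index(), terms).set_index(trial_info.index)
    folds = assign_folds(trial_info.reset_index()).to_numpy()

    n_rot, n_tp, n_eff = n_folds, len(timepoints), len(terms)
    tmat = np.full((n_rot, n_tp, n_eff), np.nan)
    dfmat = np.full((n_rot, n_tp, n_eff), np.nan)
    est = np.full((n_rot, n_tp, n_eff), np.nan)

    groups_all = wide.index.get_level_values("participant").to_numpy()
    Xall, names = build_design(coded)
    eff_cols = [names.index(t) for t in terms]

    for r in range(n_rot):
        train = folds != (r + 1)
        for k in range(n_tp):
            y = wide.iloc[:, k].to_numpy(dtype=float)
            rows = train & ~np.isnan(y)
            if rows.sum() < Xall.shape[1] + 2:
                continue
            try:
                fit = fit_random_intercept(
                    Xall[rows], y[rows], groups_all[rows], names=names, reml=reml
                )
            except np.linalg.LinAlgError:
                continue
            tmat[r, k] = fit.tvalues[eff_cols]
            dfmat[r, k] = fit.df[eff_cols]
            est[r, k] = fit.params[eff_cols]

    stats = TimepointStats(timepoints, terms, tmat, dfmat, est)

    # leakage guard: selection statistics exist for training folds only
    assert tmat.shape[0] == n_folds

    selected: dict[str, dict[int, float]] = {t: {} for t in terms}
    final_fits: dict[str, MixedLMResult] = {}
    for e, term in enumerate(terms):
        yvals = np.full(len(wide), np.nan)
        for r in range(n_rot):
            with np.errstate(invalid="ignore"):
                absrow = np.abs(tmat[r, :, e])
            if np.all(np.isnan(absrow)):
                continue
            k_star = int(np.nanargmax(absrow))
            selected[term][r + 1] = float(timepoints[k_star])
            test = folds == (r + 1)
            yvals[test] = wide.iloc[:, k_star].to_numpy(dtype=float)[test]
        rows = ~np.isnan(yvals)
        fit = fit_random_intercept(
            Xall[rows], yvals[rows], groups_all[rows], names=names, reml=reml
        )
        final_fits[term] = fit

    clusters = consensus_clusters(stats, consensus_threshold)
    if fit_cluster_models:
        for cl in clusters:
            in_win = (timepoints >= cl.t_start) & (timepoints <= cl.t_end)
            ymean = np.nanmean(wide.to_numpy(dtype=float)[:, in_win], axis=1)
            rows = ~np.isnan(ymean)
            try:
                cl.window_fit = fit_random_intercept(
                    Xall[rows], ymean[rows], groups_all[rows], names=names, reml=reml
                )
            except np.linalg.LinAlgError:
                cl.window_fit = None

    return CvLmemResult(terms, selected, final_fits, stats, clusters)


def consensus_clusters(
    stats: TimepointStats, threshold: float = T_CONSENSUS
) -> list[ConsensusCluster]:
    """Maximal contiguous runs of timepoints where every rotation shows
    |t| > threshold, per effect."""
    out: list[ConsensusCluster] = []
    for e, term in enumerate(stats.effects):
        with np.errstate(invalid="ignore"):
            ok = np.all(np.abs(stats.t[:, :, e]) > threshold, axis=0)
        ok &= ~np.any(np.isnan(stats.t[:, :, e]), axis=0)
        k = 0
        while k < len(ok):
            if ok[k]:
                start = k
                while k < len(ok) and ok[k]:
                    k += 1
                seg = np.abs(stats.t[:, start:k, e])
                out.append(
                    ConsensusCluster(
                        term,
                        float(stats.timepoints[start]),
                        float(stats.timepoints[k - 1]),
                        float(np.min(seg)),
                    )
                )
            else:
                k += 1
    return out


def liberal_scan(
    long: pd.DataFrame,
    effect_spec: str | list[str],
    reml: bool = False,
) -> pd.DataFrame:
    """Per-timepoint mixed models on the full data with no multiplicity
    correction: one row per (time, effect) with t, df and p.  The minimum p
    per effect (`.attrs['min_p']`) bounds what the robust procedure could
    have missed."""
    terms = expand_terms(effect_spec)
    wide, trial_info = _pivot(long)
    coded = code_covariates(trial_info.reset_index(), terms).set_index(trial_info.index)
    Xall, names = build_design(coded)
    groups_all = wide.index.get_level_values("participant").to_numpy()
    eff_cols = [names.index(t) for t in terms]

    rows = []
    for k, tp in enumerate(wide.columns):
        y = wide.iloc[:, k].to_numpy(dtype=float)
        use = ~np.isnan(y)
        if use.sum() < Xall.shape[1] + 2:
            continue
        try:
            fit = fit_random_intercept(
                Xall[use], y[use], groups_all[use], names=names, reml=reml
            )
        except np.linalg.LinAlgError:
            continue
        for term, j in zip(terms, eff_cols):
            rows.append(
                {
                    "time": float(tp), "effect": term,
                    "t": fit.tvalues[j], "df": fit.df[j], "p": fit.pvalues[j],
                }
            )
    scan = pd.DataFrame(rows)
    scan.attrs["min_p"] = {
        term: (
            float(sub["p"].min()),
            float(sub.loc[sub["p"].idxmin(), "time"]),
        )
        for term, sub in scan.groupby("effect")
    }
    return scan
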