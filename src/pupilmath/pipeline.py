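"""End-to-end pipeline: raw traces -> preprocessing -> trial features ->
crossvalidated timecourse models -> best-subset feature models ->
psychometric descriptives, with a results bundle on disk."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import cvlmem, modelsel, preprocess, psychometrics
from .config import AnalysisConfig
from .design import PhaseTimeline
from .preprocess import ParticipantResult, RawTrace
from .design import TrialPlan

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: AnalysisConfig
    qc: pd.DataFrame
    features: pd.DataFrame
    long: pd.DataFrame
    cv_results: dict[str, cvlmem.CvLmemResult]
    model_reports: dict[str, modelsel.ComparisonReport]
    descriptives: pd.DataFrame
    participant_results: list[ParticipantResult] = field(repr=False, default_factory=list)


def epoched_to_long(
    results: list[ParticipantResult],
    trial_table: pd.DataFrame,
    horizon_quantile: float = 0.90,
    covariates: tuple[str, ...] = ("cue", "accuracy", "amas", "tai", "stai"),
) -> pd.DataFrame:
    """Long analysis table (participant, trial, time, pupil + covariates)
    for the first part, on the common 25 ms grid up to the chosen quantile
    of first-part durations."""
    durations = [
        t.bin_centers_ms[t.part == 1].max()
        for r in results for t in r.trials if t.kept and len(t.bin_centers_ms)
    ]
    horizon = float(np.quantile(durations, horizon_quantile))
    cov = trial_table.set_index(["participant", "trial"])
    rows = []
    for r in results:
        for t in r.trials:
            if not t.kept:
                continue
            seg = (t.part == 1) & (t.bin_centers_ms <= horizon)
            key = (t.participant, t.trial_index)
            if key not in cov.index:
                continue
            meta = cov.loc[key]
            base = {
                "participant": t.participant,
                "trial": t.trial_index,
                **{c: meta[c] for c in covariates if c in meta},
            }
            for tm, v in zip(t.bin_centers_ms[seg], t.pupil[seg]):
                rows.append({**base, "time": float(tm) / 1000.0, "pupil": float(v)})
    return pd.DataFrame(rows)


def merge_questionnaires(
    trial_table: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    cols = [c for c in ("amas", "tai", "stai", "pmp") if c in participants]
    return trial_table.merge(
        participants[["participant", *cols]], on="participant", how="left"
    )


def timecourse_plot(long: pd.DataFrame, path: Path, split_by: str = "amas") -> None:
    """Per-bin mean +/- SEM pupil timecourse by cue, split at the median of
    `split_by` (plotting only; inference is parametric)."""
    df = long.copy()
    df["group"] = np.where(
        df[split_by] > df[split_by].median(), f"high {split_by}", f"low {split_by}"
    )
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for (grp, cue), sub in df.groupby(["group", "cue"]):
        agg = sub.groupby("time")["pupil"].agg(["mean", "sem"])
        ax.plot(agg.index, agg["mean"], label=f"{grp}, {cue}")
        ax.fill_between(
            agg.index, agg["mean"] - agg["sem"], agg["mean"] + agg["sem"], alpha=0.2
        )
    tl = PhaseTimeline()
    for onset in (tl.cue_onset, tl.multiplicand_onset, tl.second_number_offset,
                  tl.min_response_offset):
        ax.axvline(onset / 1000.0, color="gray", ls="--", lw=0.6)
    ax.set_xlabel("time from trial onset (s)")
    ax.set_ylabel("pupil size (z, baseline-aligned)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(
    config: AnalysisConfig,
    traces: dict[tuple[str, int], RawTrace],
    trial_table: pd.DataFrame,
    participants: pd.DataFrame,
    plans: dict[tuple[str, int], TrialPlan] | None = None,
    item_tables: dict[str, np.ndarray] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage; any failure aborts with the stage name and the
    config hash."""
    stage = "preprocess"
    try:
        by_participant: dict[str, dict[int, RawTrace]] = {}
        for (pid, trial), trace in traces.items():
            by_participant.setdefault(pid, {})[trial] = trace
        results = [
            preprocess.preprocess_participant(
                pid,
                trs,
                plans={t: plans[(pid, t)] for t in trs} if plans else None,
                velocity_k=config.velocity_k,
                spline_lam=config.spline_lam,
                bin_ms=config.bin_ms,
                missing_threshold=config.missing_threshold,
                baseline_cutoff_sd=config.baseline_cutoff_sd,
            )
            for pid, trs in sorted(by_participant.items())
        ]
        qc = preprocess.qc_summary(results)

        stage = "features"
        feats = pd.DataFrame(
            [preprocess.participant_features(r, trial_table) for r in results]
        ).merge(participants, on="participant", how="left")

        stage = "timecourse"
        trial_cov = merge_questionnaires(trial_table, participants)
        long = epoched_to_long(results, trial_cov, config.grid_horizon_quantile)
        cv_results = {
            config.effects: cvlmem.crossvalidated_effect_test(
                long, config.effects,
                n_folds=config.n_folds,
                consensus_threshold=config.consensus_t,
                reml=config.reml,
            )
        }

        stage = "modelsel"
        model_reports = {}
        for outcome in config.outcomes:
            if outcome in feats and feats[outcome].std() > 0:
                model_reports[outcome] = modelsel.rank_models(
                    feats, outcome,
                    predictors=tuple(
                        p for p in modelsel.FEATURE_COLUMNS if p in feats
                    ),
                )

        stage = "psychometrics"
        desc_cols = tuple(
            c for c in ("amas", "tai", "stai", "pmp", "accuracy",
                        "peak_latency", "max_dilation") if c in feats
        )
        descriptives = psychometrics.describe_battery(feats, desc_cols, item_tables)
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config {config.hash}): {err}"
        ) from err

    result = PipelineResult(
        config, qc, feats, long, cv_results, model_reports, descriptives, results
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        qc.to_csv(out / "qc.csv", index=False)
        feats.to_csv(out / "features.csv", index=False)
        descriptives.to_csv(out / "descriptives.csv", index=False)
        for outcome, rep in model_reports.items():
            rep.table.to_csv(out / f"models_{outcome}.csv", index=False)
        rows = []
        for spec_name, cv in cv_results.items():
            for eff in cv.effects:
                t, df_, p = cv.effect_test(eff)
                rows.append({"effects": spec_name, "effect": eff,
                             "t": t, "df": df_, "p": p})
        pd.DataFrame(rows).to_csv(out / "timecourse_tests.csv", index=False)
        if "amas" in long:
            timecourse_plot(long, out / "timecourse.png")
        manifest = {
            "config_hash": config.hash,
            "seed": config.seed,
            "files": sorted(p.name for p in out.iterdir()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        logger.info("results written to %s (config %s)", out, config.hash)
    return result
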