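"""Delimited-text table formats.

Everything is plain CSV; schemas are identified by column names, so column
order is free.  Tables:

- samples: participant, trial, part, time_ms, pupil_au, valid  (500 Hz)
- trials: participant, trial, cue, multiplicand, multiplier, accuracy,
  response_time_ms
- items: participant, questionnaire, item, response
- participants: participant + questionnaire totals and trait summaries
- features: participant, accuracy, pmp, baseline_ps, max_dilation,
  peak_latency, ...
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawTrace
from .synthgen import CohortData, ParticipantProfile

SCHEMAS = {
    "samples": ["participant", "trial", "part", "time_ms", "pupil_au", "valid"],
    "trials": ["participant", "trial", "cue", "multiplicand", "multiplier",
               "accuracy", "response_time_ms"],
    "items": ["participant", "questionnaire", "item", "response"],
    "participants": ["participant", "amas", "tai", "stai", "pmp"],
    "features": ["participant", "accuracy", "baseline_ps", "max_dilation",
                 "peak_latency"],
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a CSV and validate it against the named schema.

    Missing columns raise with the full list; malformed rows are reported
    with their line numbers.
    """
    required = SCHEMAS[kind]
    try:
        # round_trip parsing keeps write->read->write byte-stable
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed CSV ({err})") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} for schema {kind!r}")
    bad = df[required].isna().all(axis=1)
    if bad.any():
        first = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
        raise ValueError(f"{path}: empty/malformed row at line {first}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, kind: str | None = None) -> None:
    if kind is not None:
        missing = [c for c in SCHEMAS[kind] if c not in df.columns]
        if missing:
            raise ValueError(f"refusing to write {kind!r} without columns {missing}")
    df.to_csv(path, index=False)


def samples_frame(data: CohortData) -> pd.DataFrame:
    rows = []
    for (pid, trial), trace in data.traces.items():
        rows.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "trial": trial,
                    "part": trace.part,
                    "time_ms": trace.time_ms,
                    "pupil_au": trace.pupil_au,
                    "valid": trace.valid.astype(int),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["participant", "trial", "part", "time_ms"]).reset_index(drop=True)


def items_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for q, arr in p.items.items():
            for j, r in enumerate(arr):
                rows.append(
                    {"participant": p.participant_id, "questionnaire": q,
                     "item": j + 1, "response": int(r)}
                )
    return pd.DataFrame(rows)


def traces_from_samples(samples: pd.DataFrame) -> dict[tuple[str, int], RawTrace]:
    traces = {}
    for (pid, trial), g in samples.groupby(["participant", "trial"], sort=True):
        g = g.sort_values(["part", "time_ms"])
        traces[(pid, int(trial))] = RawTrace(
            time_ms=g["time_ms"].to_numpy(dtype=float),
            pupil_au=g["pupil_au"].to_numpy(dtype=float),
            valid=g["valid"].to_numpy().astype(bool),
            part=g["part"].to_numpy(dtype=int),
        )
    return traces


def write_cohort(data: CohortData, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as the documented CSV set; round-trips
    losslessly through the readers here."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / "participants.csv",
        "trials": out / "trials.csv",
        "items": out / "items.csv",
    }
    write_table(data.participants, paths["participants"], "participants")
    write_table(data.trials, paths["trials"], "trials")
    write_table(items_frame(data.profiles), paths["items"], "items")
    if data.traces:
        paths["samples"] = out / "samples.csv"
        write_table(samples_frame(data), paths["samples"], "samples")
    return paths
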