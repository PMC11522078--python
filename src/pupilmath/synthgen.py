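"""Synthetic cohort generator.

Emulates the data a pupillometry study of math anxiety during mental
multiplication would collect: per-participant questionnaire scores (AMAS,
TAI, STAI trait, PMP) with realistic internal consistency, per-trial
accuracy and response times, and raw 500 Hz pupil traces with blinks.  The
between-participant correlation structure is imposed through a Gaussian
copula: latent traits are drawn from a multivariate normal whose
correlation matrix is the (reliability-disattenuated) target matrix, then
mapped to each measure's scale by monotone transforms, so that the
*observed* scores reproduce the target correlations as the cohort grows.

The pupil trace of a trial is tonic baseline + evoked dilation + AR(1)
noise.  The evoked component is a gamma-shaped effort kernel starting at
calculation onset whose peak time is the participant's per-difficulty
expected latency (longer for hard problems and for low-efficiency
participants) and whose amplitude grows with difficulty; hard cues add a
small anticipatory bump, and incorrect feedback adds a dilation bump in
the feedback phase.  Blinks appear as tracker-invalid gaps flanked by
high-velocity edge samples.  A null-cohort switch removes every
trait-pupil and difficulty-pupil coupling (one common kernel for all
trials) for type-I-error calibration of the downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit
from scipy.stats import norm

from .design import (
    MIN_RESPONSE_MS,
    TrialPlan,
    generate_session,
    with_response,
)
from .preprocess import SAMPLE_MS, RawTrace

TRAITS = ("amas", "tai", "stai", "pmp", "accuracy", "latency")

#: target correlations between observed measures.  Pinned pairs follow the
#: study conditions being emulated (AMAS row and the latency column); the
#: remaining pairs are plausible values for this population, fixed once.
DEFAULT_TARGET_CORRELATIONS = pd.DataFrame(
    [
        # amas   tai   stai   pmp    acc    lat
        [1.00, 0.41, 0.23, -0.30, -0.36, 0.48],   # amas
        [0.41, 1.00, 0.55, -0.15, -0.15, 0.42],   # tai
        [0.23, 0.55, 1.00, -0.05, -0.05, 0.14],   # stai
        [-0.30, -0.15, -0.05, 1.00, 0.45, -0.30], # pmp
        [-0.36, -0.15, -0.05, 0.45, 1.00, -0.55], # accuracy
        [0.48, 0.42, 0.14, -0.30, -0.55, 1.00],   # latency
    ],
    index=TRAITS,
    columns=TRAITS,
)

#: effective reliability of each observed measure w.r.t. its latent trait,
#: used to disattenuate the copula correlations; values fixed by one
#: Monte-Carlo calibration of the generator at n = 50000.
TRAIT_RELIABILITY = {
    "amas": 0.89,
    "tai": 0.93,
    "stai": 0.90,
    "pmp": 0.85,
    "accuracy": 0.94,
    "latency": 0.97,
}


@dataclass(frozen=True)
class QuestionnaireSpec:
    """Item structure of one questionnaire (Likert unless binary)."""

    name: str
    n_items: int
    item_min: int
    item_max: int
    item_mean: float
    item_sd: float
    alpha: float            # target internal consistency

    @property
    def total_range(self) -> tuple[int, int]:
        return self.n_items * self.item_min, self.n_items * self.item_max

    @property
    def inter_item_r(self) -> float:
        """Average inter-item correlation implied by the alpha target."""
        return self.alpha / (self.n_items - self.alpha * (self.n_items - 1))


AMAS_SPEC = QuestionnaireSpec("amas", 9, 1, 5, 2.65, 1.17, 0.89)
TAI_SPEC = QuestionnaireSpec("tai", 20, 1, 4, 2.20, 0.95, 0.93)
STAI_SPEC = QuestionnaireSpec("stai", 20, 1, 4, 2.30, 0.85, 0.90)


@dataclass
class CohortConfig:
    n_participants: int = 70
    target_correlations: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_TARGET_CORRELATIONS.copy()
    )
    questionnaires: tuple[QuestionnaireSpec, ...] = (AMAS_SPEC, TAI_SPEC, STAI_SPEC)
    # PMP: 30 binary items; per-item success probabilities and latent loading
    pmp_n_items: int = 30
    pmp_p_range: tuple[float, float] = (0.66, 0.98)
    pmp_loading2: float = 0.5
    # task accuracy: per-difficulty logistic link on the accuracy trait
    easy_accuracy: float = 0.90
    hard_accuracy: float = 0.61
    accuracy_slope: float = 1.0
    # peak latency (s from the offset of the second number)
    easy_latency_mean: float = 8.9
    easy_latency_sd: float = 3.0
    hard_latency_mean: float = 15.5
    hard_latency_sd: float = 6.4
    latency_clip: tuple[float, float] = (2.0, 28.0)
    # pupil trace, arbitrary eye-tracker units
    baseline_mean: float = 4000.0
    baseline_sd: float = 600.0
    dilation_gain: float = 300.0        # easy-trial peak amplitude, a.u.
    hard_gain_factor: float = 1.35
    anticipation_gain: float = 60.0     # hard-cue anticipatory bump, a.u.
    feedback_gain: float = 120.0        # error-feedback bump, a.u.
    kernel_shape: float = 3.0
    ar_coefficient: float = 0.995
    innovation_sd: float = 2.0
    # slow tonic drift (arousal/hippus band): OU process, time constant s
    drift_tau_s: float = 20.0
    drift_sd: float = 60.0
    # blinks
    blink_rate_hz: float = 0.15
    blink_duration_ms: tuple[float, float] = (100.0, 400.0)
    # switches
    null_cohort: bool = False
    disattenuate: bool = True
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ParticipantProfile:
    participant_id: str
    latent: dict[str, float]
    items: dict[str, np.ndarray]
    totals: dict[str, int]
    easy_accuracy_p: float
    hard_accuracy_p: float
    easy_latency_s: float
    hard_latency_s: float
    tonic_baseline_au: float
    accuracy_trait: float          # expected overall accuracy rate


def check_correlation_matrix(C: np.ndarray) -> None:
    """Reject asymmetric, non-unit-diagonal, or non-PSD target matrices,
    naming the offending eigenvalue."""
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semi-definite: "
            f"smallest eigenvalue {w.min():.6g}"
        )


def latent_correlations(config: CohortConfig) -> np.ndarray:
    """Copula correlation matrix: targets disattenuated by the measures'
    reliabilities so that observed scores recover the targets."""
    C = config.target_correlations.loc[list(TRAITS), list(TRAITS)].to_numpy(dtype=float)
    check_correlation_matrix(C)
    if not config.disattenuate:
        return C
    rel = np.array([TRAIT_RELIABILITY[t] for t in TRAITS])
    scale = 1.0 / np.sqrt(np.outer(rel, rel))
    np.fill_diagonal(scale, 1.0)
    CL = C * scale
    check_correlation_matrix(CL)
    return CL


def _likert_items(
    z: np.ndarray, spec: QuestionnaireSpec, rng: np.random.Generator
) -> np.ndarray:
    """(n, k) integer item responses with the alpha-implied common factor."""
    n = len(z)
    rho = spec.inter_item_r
    x = np.sqrt(rho) * z[:, None] + np.sqrt(1 - rho) * rng.standard_normal(
        (n, spec.n_items)
    )
    raw = np.rint(spec.item_mean + spec.item_sd * x)
    return np.clip(raw, spec.item_min, spec.item_max).astype(int)


def _pmp_items(z: np.ndarray, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    n = len(z)
    p = np.linspace(*config.pmp_p_range, config.pmp_n_items)
    tau = norm.ppf(1 - p)
    load = np.sqrt(config.pmp_loading2)
    x = load * z[:, None] + np.sqrt(1 - config.pmp_loading2) * rng.standard_normal(
        (n, config.pmp_n_items)
    )
    return (x > tau[None, :]).astype(int)


def simulate_cohort(config: CohortConfig) -> list[ParticipantProfile]:
    """Draw the cohort's participant profiles from the Gaussian copula."""
    rng = config.rng()
    CL = latent_correlations(config)
    w, V = np.linalg.eigh(CL)
    L = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    Z = rng.standard_normal((config.n_participants, len(TRAITS))) @ L.T
    zmap = dict(zip(TRAITS, Z.T))

    items: dict[str, np.ndarray] = {}
    for spec in config.questionnaires:
        items[spec.name] = _likert_items(zmap[spec.name], spec, rng)
    items["pmp"] = _pmp_items(zmap["pmp"], config, rng)

    easy_p = expit(logit(config.easy_accuracy) + config.accuracy_slope * zmap["accuracy"])
    hard_p = expit(logit(config.hard_accuracy) + config.accuracy_slope * zmap["accuracy"])
    easy_lat = np.clip(
        config.easy_latency_mean + config.easy_latency_sd * zmap["latency"],
        *config.latency_clip,
    )
    hard_lat = np.clip(
        config.hard_latency_mean + config.hard_latency_sd * zmap["latency"],
        *config.latency_clip,
    )
    baseline = np.maximum(
        rng.normal(config.baseline_mean, config.baseline_sd, config.n_participants),
        500.0,
    )

    profiles = []
    for i in range(config.n_participants):
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i + 1:03d}",
                latent={t: float(Z[i, j]) for j, t in enumerate(TRAITS)},
                items={k: v[i] for k, v in items.items()},
                totals={k: int(v[i].sum()) for k, v in items.items()},
                easy_accuracy_p=float(easy_p[i]),
                hard_accuracy_p=float(hard_p[i]),
                easy_latency_s=float(easy_lat[i]),
                hard_latency_s=float(hard_lat[i]),
                tonic_baseline_au=float(baseline[i]),
                accuracy_trait=float((easy_p[i] + hard_p[i]) / 2.0),
            )
        )
    return profiles


def cohort_table(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    """Per-participant summary table of the generated measures."""
    return pd.DataFrame(
        {
            "participant": [p.participant_id for p in profiles],
            "amas": [p.totals["amas"] for p in profiles],
            "tai": [p.totals["tai"] for p in profiles],
            "stai": [p.totals["stai"] for p in profiles],
            "pmp": [p.totals["pmp"] for p in profiles],
            "accuracy_trait": [p.accuracy_trait for p in profiles],
            "easy_latency_s": [p.easy_latency_s for p in profiles],
            "hard_latency_s": [p.hard_latency_s for p in profiles],
            "tonic_baseline_au": [p.tonic_baseline_au for p in profiles],
        }
    )


# ------------------------------------------------------------- trace model

def gamma_kernel(t_s: np.ndarray, peak_s: float, shape: float) -> np.ndarray:
    """Gamma-density-shaped kernel normalised to peak 1 at `peak_s`."""
    out = np.zeros_like(t_s, dtype=float)
    pos = t_s > 0
    tp = max(peak_s, 1e-6)
    a = shape
    tt = t_s[pos] / tp
    out[pos] = tt ** (a - 1) * np.exp(-(a - 1) * (tt - 1))
    return out


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.normal(0, sd, n)
    x = lfilter([1.0], [1.0, -phi], innov)
    if phi < 1:
        x += rng.normal(0, sd / np.sqrt(1 - phi**2)) * phi ** np.arange(n)
    return x


def _insert_blinks(
    pupil: np.ndarray, valid: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> None:
    """In-place: tracker-invalid gaps with sharp partial-occlusion edges."""
    n = len(pupil)
    duration_s = n * SAMPLE_MS / 1000.0
    n_blinks = rng.poisson(config.blink_rate_hz * duration_s)
    for _ in range(n_blinks):
        dur = rng.uniform(*config.blink_duration_ms)
        width = max(int(dur / SAMPLE_MS), 2)
        start = int(rng.integers(0, max(n - width, 1)))
        stop = min(start + width, n)
        valid[start:stop] = False
        pupil[start:stop] = 0.0
        edge = 3  # partial-occlusion samples: large sample-to-sample velocity
        lo = max(start - edge, 0)
        pupil[lo:start] *= np.linspace(0.8, 0.2, start - lo)
        hi = min(stop + edge, n)
        pupil[stop:hi] *= np.linspace(0.2, 0.8, hi - stop)


def simulate_trial(
    profile: ParticipantProfile,
    plan: TrialPlan,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
) -> tuple[RawTrace, int, float]:
    """One trial's raw 500 Hz trace, its accuracy (0/1), and the response
    time in ms from the offset of the second number."""
    config = config or CohortConfig()
    hard = plan.cue.value == "hard"

    if config.null_cohort:
        p_correct = 0.75
        latency_s = 10.0
        amp = config.dilation_gain
    else:
        p_correct = profile.hard_accuracy_p if hard else profile.easy_accuracy_p
        latency_s = profile.hard_latency_s if hard else profile.easy_latency_s
        latency_s = float(
            np.clip(latency_s + rng.normal(0, 0.05 * latency_s), *config.latency_clip)
        )
        amp = config.dilation_gain * (config.hard_gain_factor if hard else 1.0)
        amp *= rng.lognormal(0, 0.1)
    accuracy = int(rng.random() < p_correct)

    response_ms = max(
        float(MIN_RESPONSE_MS), latency_s * 1000.0 + rng.uniform(500.0, 2500.0)
    )
    plan = with_response(plan, response_ms)
    tl = plan.timeline

    t1 = np.arange(0.0, tl.response_end, SAMPLE_MS)
    t2 = np.arange(0.0, tl.second_part_end, SAMPLE_MS)
    n1, n2 = len(t1), len(t2)

    calc_onset_s = tl.second_number_offset / 1000.0
    pupil1 = np.full(n1, profile.tonic_baseline_au)
    pupil1 += amp * gamma_kernel(t1 / 1000.0 - calc_onset_s, latency_s, config.kernel_shape)
    if hard and not config.null_cohort:
        cue_s = tl.cue_onset / 1000.0
        pupil1 += config.anticipation_gain * gamma_kernel(
            t1 / 1000.0 - cue_s, 1.5, config.kernel_shape
        )

    pupil2 = np.full(n2, profile.tonic_baseline_au)
    if accuracy == 0 and not config.null_cohort:
        fb_s = tl.feedback_sound_onset / 1000.0
        pupil2 += config.feedback_gain * gamma_kernel(
            t2 / 1000.0 - fb_s, 1.2, config.kernel_shape
        )

    noise = _ar1(n1 + n2, config.ar_coefficient, config.innovation_sd, rng)
    if config.drift_sd > 0:
        phi_d = float(np.exp(-SAMPLE_MS / 1000.0 / config.drift_tau_s))
        noise += _ar1(n1 + n2, phi_d, config.drift_sd * np.sqrt(1 - phi_d**2), rng)
    pupil1 += noise[:n1]
    pupil2 += noise[n1:]

    valid1 = np.ones(n1, dtype=bool)
    valid2 = np.ones(n2, dtype=bool)
    if config.blink_rate_hz > 0:
        _insert_blinks(pupil1, valid1, config, rng)
        _insert_blinks(pupil2, valid2, config, rng)

    trace = RawTrace(
        time_ms=np.concatenate([t1, t2]),
        pupil_au=np.concatenate([pupil1, pupil2]),
        valid=np.concatenate([valid1, valid2]),
        part=np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)]),
    )
    return trace, accuracy, response_ms


@dataclass
class CohortData:
    """Everything one simulated study produces."""

    config: CohortConfig
    profiles: list[ParticipantProfile]
    participants: pd.DataFrame
    trials: pd.DataFrame
    traces: dict[tuple[str, int], RawTrace]
    plans: dict[tuple[str, int], TrialPlan]


def simulate_dataset(config: CohortConfig, with_traces: bool = True) -> CohortData:
    """Full study simulation: profiles, 72-trial sessions, and (optionally)
    raw traces.  Per-participant RNG streams derive deterministically from
    the root seed, so any participant reproduces independently of cohort
    size."""
    profiles = simulate_cohort(config)
    rows = []
    traces: dict[tuple[str, int], RawTrace] = {}
    plans: dict[tuple[str, int], TrialPlan] = {}
    for i, prof in enumerate(profiles):
        pr_rng = np.random.default_rng([config.seed, 1000 + i])
        session_seed = int(pr_rng.integers(0, 2**31 - 1))
        for plan in generate_session(session_seed):
            if plan.is_practice:
                continue
            if with_traces:
                trace, acc, rt = simulate_trial(prof, plan, pr_rng, config)
                traces[(prof.participant_id, plan.trial_index)] = trace
                plans[(prof.participant_id, plan.trial_index)] = with_response(plan, rt)
            else:
                hard = plan.cue.value == "hard"
                p = prof.hard_accuracy_p if hard else prof.easy_accuracy_p
                acc = int(pr_rng.random() < (0.75 if config.null_cohort else p))
                rt = np.nan
            rows.append(
                {
                    "participant": prof.participant_id,
                    "trial": plan.trial_index,
                    "cue": plan.cue.value,
                    "multiplicand": plan.problem.multiplicand,
                    "multiplier": plan.problem.multiplier,
                    "accuracy": acc,
                    "response_time_ms": rt,
                }
            )
    return CohortData(
        config, profiles, cohort_table(profiles), pd.DataFrame(rows), traces, plans
    )


# ------------------------------------------------- epoched-scale generator

def simulate_epoched_cohort(
    n_participants: int = 20,
    n_trials: int = 24,
    grid_s: np.ndarray | None = None,
    seed: int = 0,
    cue_amp: float = 0.0,
    ma_amp: float = 0.0,
    effect_window_s: tuple[float, float] = (8.0, 14.0),
    participant_sd: float = 0.2,
    trial_sd: float = 0.28,
    noise_sd: float = 0.23,
    noise_ar: float = 0.35,
) -> tuple[pd.DataFrame, dict]:
    """Binned, z-scale pupil data generated directly on the analysis grid.

    Bypasses the raw-trace pipeline to make the Monte-Carlo studies of the
    crossvalidated mixed-model procedure affordable: pupil(t) = participant
    intercept + trial offset + cue and anxiety effects confined to a known
    time window + AR noise across the grid.  The default variance
    decomposition (trial offset vs within-trial fluctuation and its
    autocorrelation across 1.5 s grid steps) matches what the raw-trace
    pipeline produces on baseline-aligned z-scored bins.  With
    `cue_amp = ma_amp = 0` this is a null cohort.  Returns the long
    analysis table and the ground truth (effect window, amplitudes).
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid_s if grid_s is not None else np.arange(0.0, 18.0, 1.5))
    bump = np.zeros_like(grid)
    in_win = (grid >= effect_window_s[0]) & (grid <= effect_window_s[1])
    if in_win.any():
        mid = (effect_window_s[0] + effect_window_s[1]) / 2.0
        halfw = (effect_window_s[1] - effect_window_s[0]) / 2.0
        bump[in_win] = np.cos((grid[in_win] - mid) / halfw * np.pi / 2.0) ** 2

    rows = []
    for i in range(n_participants):
        pid = f"p{i + 1:03d}"
        intercept = rng.normal(0, participant_sd)
        ma = rng.normal()   # z-scored anxiety score
        for j in range(n_trials):
            cue = -0.5 if j % 2 == 0 else 0.5
            offset = rng.normal(0, trial_sd)
            innov = rng.normal(0, noise_sd * np.sqrt(1 - noise_ar**2), len(grid))
            noise = lfilter([1.0], [1.0, -noise_ar], innov)
            noise += rng.normal(0, noise_sd) * noise_ar ** np.arange(len(grid))
            signal = (cue_amp * cue + ma_amp * ma) * bump
            y = intercept + offset + signal + noise
            for k, t in enumerate(grid):
                rows.append(
                    {
                        "participant": pid,
                        "trial": j,
                        "time": float(t),
                        "pupil": float(y[k]),
                        "cue": "hard" if cue > 0 else "easy",
                        "amas": ma,
                    }
                )
    truth = {
        "effect_window_s": effect_window_s,
        "cue_amp": cue_amp,
        "ma_amp": ma_amp,
        "grid_s": grid,
    }
    return pd.DataFrame(rows), truth
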