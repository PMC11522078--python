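"""Task structure for the auditory mental-multiplication paradigm.

A session presents spoken multiplication problems of two difficulty levels.
Every problem uses a multiplicand in {12, 13, 14}; easy problems use
multipliers 6-9 and hard problems 16-19, so the 24 unique problems split
12/12 by difficulty.  Each problem is repeated three times, giving 72
experimental trials, preceded by 4 practice trials and split into two
blocks of 36.

Each trial has two parts.  The first part runs from trial onset to the
vocal response: a 750 ms pre-stimulus baseline, an auditory difficulty cue
opening a 4000 ms anticipation window, three 750 ms sounds (multiplicand,
operator, multiplier), and a 6000 ms window during which no response may
be given; the response itself can come any time after that, so first-part
duration varies across trials.  The second part re-baselines for 750 ms,
then a 750 ms confirmation sound opens a 4000 ms wait-for-feedback window,
followed by a 750 ms feedback sound inside a 4000 ms feedback window, and
a uniform 750-1250 ms inter-trial interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

MULTIPLICANDS = (12, 13, 14)
EASY_MULTIPLIERS = (6, 7, 8, 9)
HARD_MULTIPLIERS = (16, 17, 18, 19)

N_EXPERIMENTAL_TRIALS = 72
N_PRACTICE_TRIALS = 4
N_REPETITIONS = 3

# first-part phase durations, ms
BASELINE_MS = 750
ANTICIPATION_MS = 4000
SOUND_MS = 750
MIN_RESPONSE_MS = 6000
# second-part phase durations, ms
WAIT_MS = 4000
FEEDBACK_MS = 4000
ITI_RANGE_MS = (750, 1250)


class Difficulty(str, Enum):
    EASY = "easy"
    HARD = "hard"


@dataclass(frozen=True)
class ProblemSpec:
    """One multiplication problem with its difficulty label."""

    multiplicand: int
    multiplier: int

    def __post_init__(self) -> None:
        if self.multiplicand not in MULTIPLICANDS:
            raise ValueError(f"multiplicand must be in {MULTIPLICANDS}")
        if self.multiplier not in EASY_MULTIPLIERS + HARD_MULTIPLIERS:
            raise ValueError("multiplier must be in 6-9 or 16-19")

    @property
    def difficulty(self) -> Difficulty:
        return Difficulty.EASY if self.multiplier in EASY_MULTIPLIERS else Difficulty.HARD

    @property
    def correct_answer(self) -> int:
        return self.multiplicand * self.multiplier


@dataclass(frozen=True)
class PhaseTimeline:
    """Phase onsets in ms.

    First-part onsets are relative to trial onset; second-part onsets are
    relative to second-part onset (the parts cannot share one clock because
    first-part duration varies with the response).
    """

    baseline1_onset: int = 0
    cue_onset: int = BASELINE_MS
    multiplicand_onset: int = BASELINE_MS + ANTICIPATION_MS
    operator_onset: int = BASELINE_MS + ANTICIPATION_MS + SOUND_MS
    multiplier_onset: int = BASELINE_MS + ANTICIPATION_MS + 2 * SOUND_MS
    second_number_offset: int = BASELINE_MS + ANTICIPATION_MS + 3 * SOUND_MS
    min_response_offset: int = BASELINE_MS + ANTICIPATION_MS + 3 * SOUND_MS + MIN_RESPONSE_MS
    response_end: int = BASELINE_MS + ANTICIPATION_MS + 3 * SOUND_MS + MIN_RESPONSE_MS
    # second part, clock re-zeroed
    baseline2_onset: int = 0
    confirm_sound_onset: int = BASELINE_MS
    feedback_sound_onset: int = BASELINE_MS + WAIT_MS
    second_part_end: int = BASELINE_MS + WAIT_MS + FEEDBACK_MS
    iti_ms: int = 1000

    def __post_init__(self) -> None:
        if self.response_end < self.min_response_offset:
            raise ValueError("response_end precedes the minimum-response window offset")
        if not ITI_RANGE_MS[0] <= self.iti_ms <= ITI_RANGE_MS[1]:
            raise ValueError(f"ITI must lie in {ITI_RANGE_MS} ms")

    @property
    def first_part_duration_ms(self) -> int:
        return self.response_end

    @property
    def second_part_duration_ms(self) -> int:
        return self.second_part_end


#: duration of the fixed (pre-response) portion of the first part, ms
FIRST_PART_FIXED_MS = PhaseTimeline().min_response_offset  # 13000


@dataclass(frozen=True)
class TrialPlan:
    trial_index: int
    problem: ProblemSpec
    timeline: PhaseTimeline = field(default_factory=PhaseTimeline)
    is_practice: bool = False

    @property
    def cue(self) -> Difficulty:
        """The auditory difficulty cue; always valid (it matches the problem)."""
        return self.problem.difficulty


def generate_problem_set() -> list[ProblemSpec]:
    """All 24 problems: multiplicands 12-14 crossed with multipliers 6-9 and 16-19."""
    return [
        ProblemSpec(a, b)
        for a in MULTIPLICANDS
        for b in EASY_MULTIPLIERS + HARD_MULTIPLIERS
    ]


def generate_session(seed: int) -> list[TrialPlan]:
    """A full session: 4 practice trials then 72 experimental trials.

    Each of the 24 problems appears exactly three times, in a seed-determined
    random order; practice trials (2 easy + 2 hard, drawn from the same
    problem set) are prepended and flagged.  Per-trial ITIs are uniform on
    [750, 1250] ms.  The 72 experimental trials form two contiguous blocks
    of 36.
    """
    rng = np.random.default_rng(seed)
    problems = generate_problem_set()
    easy = [p for p in problems if p.difficulty is Difficulty.EASY]
    hard = [p for p in problems if p.difficulty is Difficulty.HARD]

    practice = [easy[i] for i in rng.choice(len(easy), 2, replace=False)] + [
        hard[i] for i in rng.choice(len(hard), 2, replace=False)
    ]
    experimental = problems * N_REPETITIONS
    order = rng.permutation(len(experimental))

    plans: list[TrialPlan] = []
    for idx, prob in enumerate(practice):
        iti = int(rng.integers(ITI_RANGE_MS[0], ITI_RANGE_MS[1] + 1))
        plans.append(
            TrialPlan(idx, prob, PhaseTimeline(iti_ms=iti), is_practice=True)
        )
    for rank, j in enumerate(order):
        iti = int(rng.integers(ITI_RANGE_MS[0], ITI_RANGE_MS[1] + 1))
        plans.append(
            TrialPlan(rank, experimental[j], PhaseTimeline(iti_ms=iti), is_practice=False)
        )
    return plans


def block_of(plan: TrialPlan) -> int:
    """Block number (1 or 2) of an experimental trial: contiguous halves of 36."""
    if plan.is_practice:
        raise ValueError("practice trials belong to no block")
    return 1 if plan.trial_index < N_EXPERIMENTAL_TRIALS // 2 else 2


def with_response(plan: TrialPlan, response_time_ms: float) -> TrialPlan:
    """Return a copy of `plan` whose first part ends `response_time_ms` after
    the offset of the second number (must be >= the 6000 ms minimum window)."""
    t = plan.timeline
    end = t.second_number_offset + int(round(response_time_ms))
    new_t = PhaseTimeline(response_end=end, iti_ms=t.iti_ms)
    return TrialPlan(plan.trial_index, plan.problem, new_t, plan.is_practice)
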