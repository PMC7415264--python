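"""Transformed up-down (Levitt) staircases for 2IFC threshold estimation.

Two rules are in scope:

* two-down one-up — two consecutive correct responses lower the stimulus
  level, a single error raises it.  The procedure converges on the level
  where P(correct) = sqrt(0.5) ~= 70.7%.  The default step schedule
  shrinks over the track: 3 dB until the 2nd reversal, 1 dB to the 5th,
  0.5 dB to the 8th, 0.25 dB to the 10th, 0.1 dB to the 13th, at which
  the track terminates; threshold = mean of the final 10 reversal levels.
* one-down one-up — a coarse pre-staircase (constant 1 dB step, six
  reversals) whose mean reversal level serves only to centre the prior of
  a subsequent Bayesian (Psi) track, never as a threshold estimate: for
  2IFC it targets the 50%-correct point, which is chance.

A "reversal" is a trial at which the direction of level movement flips;
the level recorded is the one presented on that trial (pre-move).  The
step in force on a trial is looked up from the number of reversals already
completed.  Levels are unbounded above and floored at -60 dB SNR to guard
runaway tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .observer import PsychometricFunction, ResponseRecord, simulate_response

__all__ = [
    "StepSchedule",
    "StaircaseRule",
    "StaircaseState",
    "StaircaseComplete",
    "InsufficientReversals",
    "ConvergenceError",
    "DEFAULT_SCHEDULE",
    "TWO_DOWN_ONE_UP",
    "ONE_DOWN_ONE_UP",
    "current_step",
    "staircase_update",
    "threshold_from_reversals",
    "run_staircase",
    "run_prestaircase",
    "staircase_calibration",
]


class StaircaseComplete(RuntimeError):
    """Raised when a step lookup or update is attempted on a finished track."""


class InsufficientReversals(ValueError):
    """Raised when fewer reversals are available than the estimator needs."""


class ConvergenceError(RuntimeError):
    """Raised when a track exceeds its trial budget without terminating."""


@dataclass(frozen=True)
class StepSchedule:
    """Piecewise-constant step sizes keyed on completed-reversal count.

    ``breakpoints`` is an ordered tuple of ``(reversal_count, step_db)``:
    the step applies until that many reversals have occurred.  The last
    breakpoint's count is the terminal reversal count of the track.
    """

    breakpoints: Tuple[Tuple[int, float], ...] = (
        (2, 3.0),
        (5, 1.0),
        (8, 0.5),
        (10, 0.25),
        (13, 0.1),
    )

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("schedule needs at least one breakpoint")
        counts = [c for c, _ in self.breakpoints]
        steps = [s for _, s in self.breakpoints]
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("reversal counts must be strictly increasing")
        if any(b >= a for a, b in zip(steps, steps[1:])):
            raise ValueError("step sizes must be strictly decreasing")
        if any(s <= 0 for s in steps):
            raise ValueError("step sizes must be positive")

    @property
    def terminal_reversals(self) -> int:
        return self.breakpoints[-1][0]


@dataclass(frozen=True)
class StaircaseRule:
    """k-down one-up decision rule (k consecutive correct -> level down)."""

    down_count: int = 2
    up_count: int = 1

    def __post_init__(self) -> None:
        if self.down_count < 1:
            raise ValueError("down_count must be >= 1")
        if self.up_count != 1:
            raise ValueError("only one-up rules are supported")


TWO_DOWN_ONE_UP = StaircaseRule(down_count=2)
ONE_DOWN_ONE_UP = StaircaseRule(down_count=1)
DEFAULT_SCHEDULE = StepSchedule()


@dataclass
class StaircaseState:
    """Evolving state of one up-down track.

    ``reversal_trials[i]`` is the trial index (1-based, parallel to
    ``trial_log``) at which the i-th reversal was recorded; it lets a
    caller split a log into pre- and post-convergence trials.
    """

    current_level_db: float
    floor_db: float = -60.0
    consecutive_correct: int = 0
    last_move: str = "none"  # "none" | "down" | "up"
    reversal_levels: List[float] = field(default_factory=list)
    reversal_trials: List[int] = field(default_factory=list)
    trial_log: List[ResponseRecord] = field(default_factory=list)

    def is_complete(self, schedule: StepSchedule) -> bool:
        return len(self.reversal_levels) >= schedule.terminal_reversals


def current_step(schedule: StepSchedule, n_reversals: int) -> float:
    """Step (dB) in force after ``n_reversals`` completed reversals."""
    if n_reversals < 0:
        raise ValueError("n_reversals must be >= 0")
    if n_reversals >= schedule.terminal_reversals:
        raise StaircaseComplete(
            f"track complete at {schedule.terminal_reversals} reversals"
        )
    for count, step in schedule.breakpoints:
        if n_reversals < count:
            return step
    raise AssertionError("unreachable")  # pragma: no cover


def staircase_update(
    state: StaircaseState,
    rule: StaircaseRule,
    schedule: StepSchedule,
    correct: bool,
) -> StaircaseState:
    """Advance the track by one response; returns the (mutated) state.

    An incorrect response raises the level by the current step and resets
    the run count; the ``down_count``-th consecutive correct lowers it.  A
    direction flip appends the pre-move level (and the current trial
    index) to the reversal log.
    """
    if state.is_complete(schedule):
        raise StaircaseComplete("update on a completed track (protocol violation)")

    move: Optional[str] = None
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= rule.down_count:
            move = "down"
            state.consecutive_correct = 0
    else:
        move = "up"
        state.consecutive_correct = 0

    if move is not None:
        step = current_step(schedule, len(state.reversal_levels))
        if state.last_move != "none" and move != state.last_move:
            state.reversal_levels.append(state.current_level_db)
            state.reversal_trials.append(len(state.trial_log))
        delta = -step if move == "down" else step
        state.current_level_db = max(state.current_level_db + delta, state.floor_db)
        state.last_move = move
    return state


def threshold_from_reversals(state: StaircaseState, k: int = 10) -> float:
    """Mean of the last ``k`` reversal levels (dB SNR)."""
    if len(state.reversal_levels) < k:
        raise InsufficientReversals(
            f"need {k} reversals, have {len(state.reversal_levels)}"
        )
    return float(np.mean(state.reversal_levels[-k:]))


def _run_track(
    pf: PsychometricFunction,
    rule: StaircaseRule,
    schedule: StepSchedule,
    start_db: float,
    rng: np.random.Generator,
    max_trials: int,
    floor_db: float,
) -> StaircaseState:
    state = StaircaseState(current_level_db=float(start_db), floor_db=floor_db)
    trial = 0
    while not state.is_complete(schedule):
        trial += 1
        if trial > max_trials:
            raise ConvergenceError(f"no convergence within {max_trials} trials")
        rec = simulate_response(pf, state.current_level_db, rng, trial_index=trial)
        state.trial_log.append(rec)
        staircase_update(state, rule, schedule, rec.correct)
    return state


def run_staircase(
    pf: PsychometricFunction,
    rule: StaircaseRule = TWO_DOWN_ONE_UP,
    schedule: StepSchedule = DEFAULT_SCHEDULE,
    start_db: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    max_trials: int = 1000,
    floor_db: float = -60.0,
    k_reversals: int = 10,
) -> Tuple[float, StaircaseState]:
    """Run a full adaptive track against a simulated observer.

    Starts at ``start_db`` (0 dB SNR by default), presents trials until
    the schedule's terminal reversal count is reached, and returns
    ``(threshold, state)`` where threshold is the mean of the final
    ``k_reversals`` reversal levels.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    state = _run_track(pf, rule, schedule, start_db, rng, max_trials, floor_db)
    return threshold_from_reversals(state, k_reversals), state


def run_prestaircase(
    pf: PsychometricFunction,
    start_db: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    step_db: float = 1.0,
    n_reversals: int = 6,
    max_trials: int = 1000,
    floor_db: float = -60.0,
) -> float:
    """Coarse one-down one-up track; returns the mean of its reversal levels.

    Intended only to centre the prior of a subsequent Psi track (for 2IFC
    the 1-down-1-up fixed point is the chance level, so this is not a
    threshold estimate).
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    schedule = StepSchedule(breakpoints=((n_reversals, step_db),))
    state = _run_track(
        pf, ONE_DOWN_ONE_UP, schedule, start_db, rng, max_trials, floor_db
    )
    return float(np.mean(state.reversal_levels))


def staircase_calibration(
    pf: PsychometricFunction,
    n_tracks: int,
    rng: np.random.Generator,
    after_reversal: int = 5,
    rule: StaircaseRule = TWO_DOWN_ONE_UP,
    schedule: StepSchedule = DEFAULT_SCHEDULE,
    start_db: float = 0.0,
) -> dict:
    """Monte-Carlo convergence summary of the two-down one-up procedure.

    Runs ``n_tracks`` seeded tracks and pools trials occurring after the
    ``after_reversal``-th reversal (the coarse-step phase excluded) to
    estimate the percent correct the rule actually tracks, alongside the
    mean reversal-based threshold.  Returns a dict with keys
    ``percent_correct``, ``mean_threshold_db``, ``n_trials_pooled`` and
    ``n_tracks``.
    """
    n_correct = 0
    n_pooled = 0
    thresholds = np.empty(n_tracks)
    for i in range(n_tracks):
        thr, state = run_staircase(
            pf, rule=rule, schedule=schedule, start_db=start_db, rng=rng
        )
        thresholds[i] = thr
        cut = state.reversal_trials[after_reversal - 1]  # trial of the k-th reversal
        post = state.trial_log[cut:]
        n_pooled += len(post)
        n_correct += sum(r.correct for r in post)
    return {
        "percent_correct": 100.0 * n_correct / n_pooled,
        "mean_threshold_db": float(thresholds.mean()),
        "n_trials_pooled": n_pooled,
        "n_tracks": n_tracks,
    }
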