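"""Simulated two-interval forced-choice (2IFC) observer.

The observer is a parametric psychometric function on the dB-SNR axis:

    P(correct | x) = gamma + (1 - gamma - lapse) * F(x; alpha, beta)

with guess rate ``gamma`` (0.5 for 2IFC — chance when the signal interval
is unknown), lapse rate ``lapse`` capping asymptotic performance at
``1 - lapse``, threshold location ``alpha`` (the level at which the
underlying sigmoid F crosses 0.5) and slope ``beta``.  Two sigmoid forms
are offered, both parameterised so that ``F(alpha) = 0.5``:

* ``logistic`` — ``F(x) = 1 / (1 + exp(-beta (x - alpha)))``.  The default:
  dB is already a logarithmic axis, so a logistic on dB is the natural
  analogue of the Weibull-on-linear-intensity convention.
* ``gumbel`` — ``F(x) = 1 - exp(-ln 2 * exp(beta (x - alpha)))``, the
  log-Weibull form common in the adaptive-estimation literature, shifted
  so its midpoint sits at ``alpha``.

Responses are Bernoulli draws from P(correct); the observer is stationary
(no learning, fatigue or bias).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "PsychometricFunction",
    "ResponseRecord",
    "prob_correct",
    "simulate_response",
    "level_at_p",
    "write_response_csv",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class PsychometricFunction:
    """2IFC performance curve on the dB-SNR axis.

    Parameters
    ----------
    alpha:
        Threshold location in dB SNR: the level where the underlying
        sigmoid F equals 0.5, i.e. where P(correct) is midway between
        the guess floor and the lapse ceiling.
    beta:
        Slope (per dB), strictly positive.
    gamma:
        Guess rate; 0.5 for 2IFC and fixed there by default.
    lapse:
        Stimulus-independent error rate in [0, 0.1]; caps performance
        at ``1 - lapse``.
    form:
        ``"logistic"`` (default) or ``"gumbel"``.
    """

    alpha: float
    beta: float
    gamma: float = 0.5
    lapse: float = 0.02
    form: str = "logistic"

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")
        if self.form not in ("logistic", "gumbel"):
            raise ValueError(f"unknown sigmoid form {self.form!r}")


@dataclass(frozen=True)
class ResponseRecord:
    """One logged 2IFC trial."""

    trial_index: int
    level_db: float
    correct: bool
    interval_chosen: str  # "first" | "second"


def _sigmoid(form: str, x: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    z = beta * (x - alpha)
    if form == "logistic":
        return expit(z)
    # gumbel (log-Weibull), shifted so F(alpha) = 0.5; clip keeps exp finite
    return 1.0 - np.exp(-_LN2 * np.exp(np.minimum(z, 700.0)))


def prob_correct(pf: PsychometricFunction, level_db):
    """Probability of a correct 2IFC response at ``level_db`` (dB SNR).

    Accepts a scalar or array of levels; returns the same shape.
    """
    x = np.asarray(level_db, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("stimulus level must be finite")
    p = pf.gamma + (1.0 - pf.gamma - pf.lapse) * _sigmoid(pf.form, x, pf.alpha, pf.beta)
    return float(p) if np.isscalar(level_db) else p


def level_at_p(pf: PsychometricFunction, p: float) -> float:
    """Invert the psychometric function: the dB SNR where P(correct) = ``p``.

    ``p`` must lie strictly inside (gamma, 1 - lapse); the guess floor and
    lapse ceiling are only reached in the limits.
    """
    lo, hi = pf.gamma, 1.0 - pf.lapse
    if not (lo < p < hi):
        raise ValueError(f"p={p} outside the attainable open interval ({lo}, {hi})")
    q = (p - lo) / (hi - lo)  # target value of F in (0, 1)
    if pf.form == "logistic":
        z = np.log(q / (1.0 - q))
    else:
        z = np.log(-np.log1p(-q) / _LN2)
    return float(pf.alpha + z / pf.beta)


def simulate_response(
    pf: PsychometricFunction,
    level_db: float,
    rng: np.random.Generator,
    trial_index: int = 1,
) -> ResponseRecord:
    """Draw one Bernoulli 2IFC response from the observer.

    The signal interval is drawn uniformly; a correct response selects it,
    an incorrect response selects the other.  Streams are bit-reproducible
    for a given seeded ``rng``.
    """
    p = prob_correct(pf, float(level_db))
    target = int(rng.integers(2))  # 0 = first interval carries the signal
    correct = bool(rng.random() < p)
    chosen = target if correct else 1 - target
    return ResponseRecord(
        trial_index=trial_index,
        level_db=float(level_db),
        correct=correct,
        interval_chosen="first" if chosen == 0 else "second",
    )


def write_response_csv(records: Iterable[ResponseRecord], path) -> None:
    """Serialize a trial log to CSV (trial_index, level_db, correct, interval_chosen)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_index", "level_db", "correct", "interval_chosen"])
        for r in records:
            w.writerow([r.trial_index, r.level_db, r.correct, r.interval_chosen])
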