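"""Statistical suite for paired threshold comparisons.

Implements the inference toolkit used for small-n within-subject
psychophysics:

* subject-wise sign-flip permutation tests for directional paired
  hypotheses (10,000 permutations by default, with exact enumeration of
  all 2^n flip patterns for small samples);
* Benjamini–Hochberg false-discovery-rate control across a comparison
  family;
* a Dienes-style Bayes factor for non-significant paired differences,
  with a Uniform(0, h1_upper) dB effect prior under H1 and a small-sample
  correction to the SEM;
* a permutation repeated-measures factorial ANOVA (object x visual cue,
  within subjects, optionally with day repetitions);
* Pearson correlation tests, paired Cohen's d, and noncentral-t power
  analysis for the one-sample t on paired differences.

The permutation p-value convention counts the unpermuted assignment as
one draw among ``n_perm``, so the attainable floor is ``1/n_perm``
(0.0001 at 10,000 permutations), and ties count toward the tail
("equal to or greater").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedSample",
    "PermResult",
    "BFResult",
    "AnovaResult",
    "PearsonResult",
    "signflip_permutation_test",
    "bh_fdr",
    "dienes_bf",
    "rm_anova_f",
    "perm_rm_anova",
    "t_from_r",
    "pearson_corr_test",
    "cohens_d_paired",
    "power_min_n",
]


@dataclass
class PairedSample:
    """Per-unit paired thresholds (dB SNR) under two conditions.

    A "unit" is an exchangeable block under the null — a subject, or a
    subject-day pair when measurements repeat across days (condition
    labels may be swapped within a unit but never across units, so
    day-blocked designs never permute across days).
    """

    subject_ids: Sequence
    a: np.ndarray
    b: np.ndarray
    block_labels: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if len(self.subject_ids) != self.a.size or self.a.size != self.b.size:
            raise ValueError("subject_ids, a and b must have equal length")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("thresholds must be finite (no missing values)")
        if self.block_labels is not None and len(self.block_labels) != self.a.size:
            raise ValueError("block_labels length mismatch")

    @property
    def diffs(self) -> np.ndarray:
        return self.a - self.b


@dataclass
class PermResult:
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    n_perm: int
    alternative: str


@dataclass
class BFResult:
    mean_diff: float
    sem: float
    corrected_sem: float
    bf: float
    h1_upper: float


@dataclass
class AnovaResult:
    effect: str
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    n_perm: int


@dataclass
class PearsonResult:
    r: float
    t: float
    df: int
    p: float


def _tail_p(null: np.ndarray, observed: float, alternative: str) -> float:
    if alternative == "greater":
        return float(np.mean(null >= observed))
    if alternative == "less":
        return float(np.mean(null <= observed))
    if alternative == "two_sided":
        return float(np.mean(np.abs(null) >= abs(observed)))
    raise ValueError(f"invalid alternative {alternative!r}")


def signflip_permutation_test(
    sample: PairedSample,
    n_perm: int = 10000,
    alternative: str = "greater",
    rng: Optional[np.random.Generator] = None,
    method: str = "auto",
) -> PermResult:
    """Sign-flip permutation test of the mean paired difference.

    Under the null the two condition labels are exchangeable within each
    unit, so each permutation flips every unit's (a, b) pair independently
    with probability 0.5 and records the group mean difference.  ``method``
    is ``"exhaustive"`` (all 2^n patterns), ``"mc"`` (Monte Carlo with the
    identity pattern counted once among ``n_perm`` draws), or ``"auto"``
    (exhaustive for n <= 12 units).
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"invalid alternative {alternative!r}")
    d = sample.diffs
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 units")
    observed = float(d.sum() / n)

    if method == "auto":
        method = "exhaustive" if n <= 12 else "mc"
    if method == "exhaustive":
        patterns = np.arange(2**n, dtype=np.int64)[:, None]
        signs = 1 - 2 * ((patterns >> np.arange(n)) & 1)  # pattern 0 = identity
        null = signs @ d / n
        null[0] = observed  # identity flip reproduces the observed statistic
        n_draws = 2**n
    elif method == "mc":
        if rng is None:
            raise ValueError("Monte-Carlo mode requires a seeded numpy Generator")
        signs = 1 - 2 * rng.integers(0, 2, size=(n_perm - 1, n))
        null = np.concatenate([[observed], signs @ d / n])
        n_draws = n_perm
    else:
        raise ValueError(f"invalid method {method!r}")

    return PermResult(
        observed_diff=observed,
        null_diffs=null,
        p_value=_tail_p(null, observed, alternative),
        n_perm=n_draws,
        alternative=alternative,
    )


def bh_fdr(p_values: Sequence[float], q: float = 0.05):
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)`` arrays; adjusted p-values are
    monotone in the raw ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def default_sem_correction(sem: float, df: int) -> float:
    """Small-sample inflation of the SEM: sem * (1 + 20 / df^2)."""
    return sem * (1.0 + 20.0 / df**2)


def dienes_bf(
    mean_diff: float,
    sem: float,
    n: int,
    h1_upper: float = 5.0,
    sem_correction=default_sem_correction,
) -> BFResult:
    """Bayes factor for a directional effect with a Uniform(0, h1_upper) prior.

    The data enter as a Gaussian likelihood for the mean difference with
    standard deviation equal to the small-sample-corrected SEM.  BF > 1
    favours H1 (an effect uniformly distributed on (0, h1_upper) dB);
    BF < 1 favours the null.  The marginal likelihood under H1 is computed
    by adaptive quadrature (abs tol 1e-12, rel tol 1e-8).
    """
    if not (sem > 0):
        raise ValueError("sem must be > 0")
    if n < 2:
        raise ValueError("need n >= 2")
    if not (h1_upper > 0):
        raise ValueError("h1_upper must be > 0")
    df = n - 1
    cs = float(sem_correction(sem, df)) if sem_correction else float(sem)

    like_h0 = stats.norm.pdf(mean_diff, loc=0.0, scale=cs)
    spike = min(max(mean_diff, 0.0), h1_upper)  # hint for narrow likelihoods
    integral, _ = integrate.quad(
        lambda delta: stats.norm.pdf(mean_diff, loc=delta, scale=cs),
        0.0,
        h1_upper,
        points=[spike],
        epsabs=1e-12,
        epsrel=1e-8,
        limit=200,
    )
    like_h1 = integral / h1_upper
    bf = float(np.inf) if like_h0 == 0 else float(like_h1 / like_h0)
    return BFResult(
        mean_diff=float(mean_diff),
        sem=float(sem),
        corrected_sem=cs,
        bf=bf,
        h1_upper=float(h1_upper),
    )


def _cell_array(
    table: pd.DataFrame,
    dv: str,
    unit_cols: Sequence[str],
    factor_a: str,
    factor_b: str,
) -> np.ndarray:
    """Pivot a long table to a (units, a_levels, b_levels) array; must be balanced."""
    pivot = table.pivot_table(
        index=list(unit_cols), columns=[factor_a, factor_b], values=dv, aggfunc="mean"
    )
    if pivot.isna().any().any():
        raise ValueError("unbalanced design: every unit needs every cell")
    a_levels = sorted(table[factor_a].unique())
    b_levels = sorted(table[factor_b].unique())
    cols = pd.MultiIndex.from_product([a_levels, b_levels])
    pivot = pivot.reindex(columns=cols)
    if pivot.isna().any().any():
        raise ValueError("unbalanced design: missing factor-level combinations")
    return pivot.to_numpy().reshape(len(pivot), len(a_levels), len(b_levels))


def rm_anova_f(Y: np.ndarray) -> Dict[str, Tuple[float, int, int]]:
    """Classical two-way repeated-measures F statistics from a cell array.

    ``Y`` has shape (units, a_levels, b_levels), fully within-unit.  Each
    effect is tested against its interaction with units (A vs AxS, B vs
    BxS, AB vs ABxS).  Returns ``effect -> (F, df_num, df_den)``.
    """
    s, a, b = Y.shape
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = s * b * np.sum((m_a - grand) ** 2)
    ss_b = s * a * np.sum((m_b - grand) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    df = {
        "A": (a - 1, (a - 1) * (s - 1)),
        "B": (b - 1, (b - 1) * (s - 1)),
        "AxB": ((a - 1) * (b - 1), (a - 1) * (b - 1) * (s - 1)),
    }
    ss_err = {"A": ss_as, "B": ss_bs, "AxB": ss_abs}
    ss_eff = {"A": ss_a, "B": ss_b, "AxB": ss_ab}
    out = {}
    for eff in ("A", "B", "AxB"):
        d1, d2 = df[eff]
        ms_eff = ss_eff[eff] / d1
        ms_err = ss_err[eff] / d2
        out[eff] = (float(ms_eff / ms_err), d1, d2)
    return out


def perm_rm_anova(
    table: pd.DataFrame,
    factor_a: str = "object",
    factor_b: str = "condition",
    dv: str = "threshold_db",
    subject_col: str = "subject_id",
    day_col: str = "day",
    n_perm: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, AnovaResult]:
    """Permutation repeated-measures factorial ANOVA.

    Units are subjects, or subject-day pairs when the table carries more
    than one day (repetitions then enter as additional within-subject
    measurements, matching the blocked design).  F statistics are the
    classical repeated-measures ratios; the null distribution is built by
    jointly shuffling the (A, B) cell labels within each unit, which is
    the natural exchangeability under "condition labels are arbitrary
    within a unit".  The observed labelling counts as one permutation.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    unit_cols = [subject_col]
    if day_col in table.columns and table[day_col].nunique() > 1:
        unit_cols.append(day_col)
    Y = _cell_array(table, dv, unit_cols, factor_a, factor_b)
    s, a, b = Y.shape

    observed = rm_anova_f(Y)
    effect_names = {"A": factor_a, "B": factor_b, "AxB": f"{factor_a}x{factor_b}"}
    counts = {eff: 1 for eff in observed}  # identity permutation included

    flat = Y.reshape(s, a * b)
    for _ in range(n_perm - 1):
        perm = rng.permuted(flat, axis=1)  # each unit's cells shuffled independently
        f_perm = rm_anova_f(perm.reshape(s, a, b))
        for eff in observed:
            if f_perm[eff][0] >= observed[eff][0]:
                counts[eff] += 1

    results = {}
    for eff, (f_val, d1, d2) in observed.items():
        results[effect_names[eff]] = AnovaResult(
            effect=effect_names[eff],
            f_value=f_val,
            df_num=d1,
            df_den=d2,
            p_value=counts[eff] / n_perm,
            n_perm=n_perm,
        )
    return results


def t_from_r(r: float, df: int) -> float:
    """t statistic of a Pearson correlation: t = r * sqrt(df) / sqrt(1 - r^2)."""
    if not (-1.0 < r < 1.0):
        raise ValueError("r must lie strictly inside (-1, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(r * np.sqrt(df) / np.sqrt(1.0 - r**2))


def pearson_corr_test(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson correlation with its t statistic (df = n - 2) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return PearsonResult(r=r, t=float(np.sign(r) * np.inf), df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return PearsonResult(r=r, t=float(t), df=df, p=float(p))


def cohens_d_paired(diffs: Sequence[float]) -> float:
    """Paired Cohen's d: mean of the differences over their SD (ddof=1)."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation of differences")
    return float(d.mean() / sd)


def _t_power(d: float, n: int, alpha: float, tails: str) -> float:
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == "one":
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def power_min_n(
    d: float,
    alpha: float = 0.05,
    power_target: float = 0.8,
    tails: str = "one",
    n_max: int = 1_000_000,
) -> int:
    """Smallest n giving a one-sample t on paired differences the target power.

    Power is computed from the noncentral t distribution with
    noncentrality d*sqrt(n) and df n-1 against the central-t critical
    value.  Defaults to one-tailed (directional hypotheses).
    """
    if not (d > 0):
        raise ValueError("d must be > 0")
    if not (0 < alpha < 1 and 0 < power_target < 1):
        raise ValueError("alpha and power_target must lie in (0, 1)")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    for n in range(2, n_max + 1):
        if _t_power(d, n, alpha, tails) >= power_target:
            return n
    raise RuntimeError("power target not reached within n_max")
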