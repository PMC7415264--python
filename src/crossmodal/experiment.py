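"""Synthetic crossmodal-study generator and end-to-end analysis driver.

Generates simulated studies with the statistical structure the inference
suite assumes: per-subject, per-object, per-condition true detection
thresholds (dB SNR) composed of an object baseline (the triangle sound is
detected at lower SNR than the tambourine), a between-subject offset, an
additive condition effect (negative = crossmodal enhancement, e.g. ~-2 dB
for the congruent object video) and day-to-day jitter.  Each design cell
is then *measured* with the study's adaptive procedure — a two-down
one-up staircase (Study-1-style designs) or a coarse pre-staircase
followed by Psi sessions (Study-2-style designs) — and the resulting
long-format threshold table feeds the permutation/FDR/Bayes-factor suite.

Responses are drawn from the psychometric observer model, not from an
audio-domain detector; trial-audio synthesis is validated independently
in :mod:`crossmodal.audio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .inference import (
    AnovaResult,
    BFResult,
    PairedSample,
    PermResult,
    bh_fdr,
    dienes_bf,
    perm_rm_anova,
    signflip_permutation_test,
)
from .observer import PsychometricFunction
from .psi import PsiGrid, aggregate_sessions, default_psi_grid, run_psi_session
from .staircase import (
    DEFAULT_SCHEDULE,
    TWO_DOWN_ONE_UP,
    StaircaseRule,
    StepSchedule,
    run_prestaircase,
    run_staircase,
)

__all__ = [
    "CONDITIONS",
    "OBJECTS",
    "EffectSpec",
    "StudyDesign",
    "Hypothesis",
    "STUDY1_HYPOTHESES",
    "StudyResults",
    "study1_design",
    "study2_design",
    "generate_true_thresholds",
    "simulate_study",
    "analyze_study",
    "enhancement_per_subject",
    "read_threshold_table",
    "write_threshold_table",
]

# The study's condition vocabulary (free-viewing and dichoptic sets).
CONDITIONS = (
    "fixation",
    "onset_cue",
    "object_video",
    "visualizer",
    "monocular_congruent",
    "monocular_incongruent",
    "cfs_congruent",
    "br_congruent",
    "br_incongruent",
)
OBJECTS = ("triangle", "tambourine")

TABLE_COLUMNS = ["subject_id", "day", "object", "condition", "method", "threshold_db"]


def _default_baselines() -> Dict[str, float]:
    return {"triangle": -16.0, "tambourine": -10.0}


def _default_condition_effects() -> Dict[str, float]:
    # dB shifts relative to the fixation baseline; negative = enhancement.
    # Stand-ins with the ordering the studies report: congruent video the
    # strongest cue, timing-only cues weaker, suppressed/incongruent ~none.
    return {
        "fixation": 0.0,
        "onset_cue": -1.0,
        "object_video": -2.0,
        "visualizer": -1.0,
        "monocular_congruent": -1.5,
        "monocular_incongruent": -0.5,
        "cfs_congruent": 0.0,
        "br_congruent": -1.0,
        "br_incongruent": -0.5,
    }


@dataclass
class EffectSpec:
    """Generator parameters: where truth comes from.

    truth(s, d, o, c) = baseline_mu[o] + subject_offset_s + condition_effects[c]
                        + day_jitter(s, d, o, c)

    with subject_offset ~ Normal(0, between_subject_sd) drawn once per
    subject and day jitter ~ Normal(0, within_subject_day_sd) per cell.
    """

    baseline_mu: Dict[str, float] = field(default_factory=_default_baselines)
    between_subject_sd: float = 3.0
    condition_effects: Dict[str, float] = field(
        default_factory=_default_condition_effects
    )
    within_subject_day_sd: float = 1.0
    beta: float = 2.0  # observer slope
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.between_subject_sd < 0 or self.within_subject_day_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        unknown = set(self.condition_effects) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition name(s): {sorted(unknown)}")


@dataclass
class StudyDesign:
    """Factorial layout and measurement protocol of one simulated study."""

    n_subjects: int
    n_days: int
    objects: Tuple[str, ...]
    conditions: Tuple[str, ...]
    method: str  # "staircase" | "psi"
    staircase_rule: StaircaseRule = TWO_DOWN_ONE_UP
    staircase_schedule: StepSchedule = DEFAULT_SCHEDULE
    start_db: float = 0.0
    psi_grid: Optional[PsiGrid] = None
    psi_n_trials: int = 45
    psi_n_analyzed: int = 44
    psi_prior_sd_db: float = 5.0

    def __post_init__(self) -> None:
        if self.method not in ("staircase", "psi"):
            raise ValueError("method must be 'staircase' or 'psi'")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition name(s): {sorted(unknown)}")


def study1_design(n_subjects: int = 18) -> StudyDesign:
    """18 subjects x 2 objects x 3 free-viewing conditions, staircase, 1 day."""
    return StudyDesign(
        n_subjects=n_subjects,
        n_days=1,
        objects=OBJECTS,
        conditions=("fixation", "onset_cue", "object_video"),
        method="staircase",
    )


def study2_design(
    n_subjects: int = 9, condition_set: str = "free_viewing"
) -> StudyDesign:
    """9 subjects x 2 objects x 5 days, Psi sessions.

    ``condition_set`` selects the free-viewing conditions (fixation,
    object video, envelope visualizer) or the dichoptic set (monocular
    congruent/incongruent, CFS, binocular-rivalry dominant/suppressed).
    """
    sets = {
        "free_viewing": ("fixation", "object_video", "visualizer"),
        "dichoptic": (
            "monocular_congruent",
            "monocular_incongruent",
            "cfs_congruent",
            "br_congruent",
            "br_incongruent",
        ),
    }
    if condition_set not in sets:
        raise ValueError("condition_set must be 'free_viewing' or 'dichoptic'")
    return StudyDesign(
        n_subjects=n_subjects,
        n_days=5,
        objects=OBJECTS,
        conditions=sets[condition_set],
        method="psi",
    )


def generate_true_thresholds(
    design: StudyDesign, effects: EffectSpec, rng: np.random.Generator
) -> Dict[Tuple[int, int, str, str], float]:
    """True threshold (dB SNR) per (subject, day, object, condition) cell."""
    for c in design.conditions:
        if c not in effects.condition_effects:
            raise KeyError(f"no condition effect specified for {c!r}")
    for o in design.objects:
        if o not in effects.baseline_mu:
            raise KeyError(f"no baseline specified for object {o!r}")
    truth = {}
    for s in range(design.n_subjects):
        offset = rng.normal(0.0, effects.between_subject_sd)
        for d in range(1, design.n_days + 1):
            for o in design.objects:
                for c in design.conditions:
                    jitter = rng.normal(0.0, effects.within_subject_day_sd)
                    truth[(s, d, o, c)] = (
                        effects.baseline_mu[o]
                        + offset
                        + effects.condition_effects[c]
                        + jitter
                    )
    return truth


def _observer(effects: EffectSpec, alpha: float) -> PsychometricFunction:
    return PsychometricFunction(alpha=alpha, beta=effects.beta, lapse=effects.lapse)


def simulate_study(
    design: StudyDesign, effects: EffectSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Measure every design cell with the design's adaptive procedure.

    Staircase designs run one full two-down one-up track per cell.  Psi
    designs run one coarse pre-staircase per (subject, object) — providing
    the Bayesian prior centre for that observer — then one 45-trial Psi
    session per (day, condition) cell; each session contributes one row,
    so day-blocked inference sees per-day thresholds and
    :func:`crossmodal.psi.aggregate_sessions` gives the across-day
    estimate.  Returns a long-format table with columns
    (subject_id, day, object, condition, method, threshold_db).
    """
    truth = generate_true_thresholds(design, effects, rng)
    rows: List[dict] = []
    if design.method == "staircase":
        for (s, d, o, c), alpha in truth.items():
            pf = _observer(effects, alpha)
            try:
                thr, _ = run_staircase(
                    pf,
                    rule=design.staircase_rule,
                    schedule=design.staircase_schedule,
                    start_db=design.start_db,
                    rng=rng,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"staircase failed in cell (subject={s}, day={d}, "
                    f"object={o}, condition={c}): {exc}"
                ) from exc
            rows.append(
                dict(
                    subject_id=s,
                    day=d,
                    object=o,
                    condition=c,
                    method="staircase",
                    threshold_db=thr,
                )
            )
    else:
        grid = design.psi_grid or default_psi_grid(lapse=effects.lapse)
        for s in range(design.n_subjects):
            for o in design.objects:
                # one coarse prior per observer, from the first cell's truth
                alpha0 = truth[(s, 1, o, design.conditions[0])]
                prior_center = run_prestaircase(
                    _observer(effects, alpha0), start_db=design.start_db, rng=rng
                )
                for d in range(1, design.n_days + 1):
                    for c in design.conditions:
                        pf = _observer(effects, truth[(s, d, o, c)])
                        try:
                            res = run_psi_session(
                                pf,
                                grid,
                                prior_center,
                                rng,
                                n_trials=design.psi_n_trials,
                                n_analyzed=design.psi_n_analyzed,
                                prior_sd_db=design.psi_prior_sd_db,
                            )
                        except Exception as exc:
                            raise RuntimeError(
                                f"psi session failed in cell (subject={s}, "
                                f"day={d}, object={o}, condition={c}): {exc}"
                            ) from exc
                        rows.append(
                            dict(
                                subject_id=s,
                                day=d,
                                object=o,
                                condition=c,
                                method="psi",
                                threshold_db=res.threshold_db,
                            )
                        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@dataclass(frozen=True)
class Hypothesis:
    """A directional paired comparison: test_condition < ref_condition.

    The statistic is the mean of (ref - test) per unit; positive values
    support the hypothesis (lower threshold = better detection).
    """

    name: str
    ref_condition: str
    test_condition: str


STUDY1_HYPOTHESES = (
    Hypothesis("object_video<fixation", "fixation", "object_video"),
    Hypothesis("object_video<onset_cue", "onset_cue", "object_video"),
    Hypothesis("onset_cue<fixation", "fixation", "onset_cue"),
)


@dataclass
class StudyResults:
    """Bundle of pairwise permutation results, FDR family and rm-ANOVA."""

    comparisons: pd.DataFrame
    anova: Dict[str, AnovaResult]
    n_perm: int

    def to_csv(self, path) -> None:
        self.comparisons.to_csv(path, index=False)

    def report(self) -> str:
        lines = ["Pairwise directional comparisons (sign-flip permutation):"]
        for _, row in self.comparisons.iterrows():
            bf = (
                f", BF={row.bayes_factor:.3g}"
                if np.isfinite(row.bayes_factor)
                else ""
            )
            lines.append(
                f"  {row.object:<11s} {row.hypothesis:<24s} "
                f"diff={row.observed_diff:+.3f} dB  p={row.p_raw:.4f}  "
                f"p_fdr={row.p_fdr:.4f}  "
                f"{'significant' if row.significant else 'n.s.'}{bf}"
            )
        lines.append("Permutation repeated-measures ANOVA:")
        for name, res in self.anova.items():
            lines.append(
                f"  {name:<20s} F({res.df_num},{res.df_den}) = "
                f"{res.f_value:.2f}, p = {res.p_value:.4f}"
            )
        return "\n".join(lines)


def _paired_sample(
    table: pd.DataFrame, obj: str, ref: str, test: str
) -> PairedSample:
    sub = table[table["object"] == obj]
    for cond in (ref, test):
        if cond not in set(sub["condition"]):
            raise ValueError(f"condition {cond!r} missing for object {obj!r}")
    wide = sub.pivot_table(
        index=["subject_id", "day"], columns="condition", values="threshold_db"
    )
    if wide[[ref, test]].isna().any().any():
        raise ValueError(f"missing cells for comparison {ref!r} vs {test!r}")
    return PairedSample(
        subject_ids=[f"{s}/d{d}" for s, d in wide.index],
        a=wide[ref].to_numpy(),
        b=wide[test].to_numpy(),
        block_labels=[d for _, d in wide.index],
    )


def analyze_study(
    table: pd.DataFrame,
    hypotheses: Sequence[Hypothesis] = STUDY1_HYPOTHESES,
    n_perm: int = 10000,
    rng: Optional[np.random.Generator] = None,
    q: float = 0.05,
    anova_n_perm: Optional[int] = None,
    perm_method: str = "mc",
) -> StudyResults:
    """Run the full inference suite on a long-format threshold table.

    Per object and directional hypothesis: a sign-flip permutation test on
    per-unit (subject, or subject-day) differences; BH-FDR across the
    whole comparison family; a Uniform(0,5)-prior Bayes factor for each
    non-significant comparison; and a permutation repeated-measures ANOVA
    over (object x condition).
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    objects = sorted(table["object"].unique())
    rows = []
    for hyp in hypotheses:
        for obj in objects:
            sample = _paired_sample(table, obj, hyp.ref_condition, hyp.test_condition)
            res = signflip_permutation_test(
                sample, n_perm=n_perm, alternative="greater", rng=rng,
                method=perm_method,
            )
            # subject-level differences (days averaged) for the Bayes factor
            subj = (
                pd.DataFrame(
                    {"subject": [s.split("/")[0] for s in sample.subject_ids],
                     "diff": sample.diffs}
                )
                .groupby("subject")["diff"]
                .mean()
            )
            rows.append(
                dict(
                    object=obj,
                    hypothesis=hyp.name,
                    observed_diff=res.observed_diff,
                    p_raw=res.p_value,
                    n_units=len(sample.diffs),
                    n_subjects=len(subj),
                    subj_mean=subj.mean(),
                    subj_sem=subj.std(ddof=1) / np.sqrt(len(subj)),
                )
            )
    comp = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(comp["p_raw"].to_numpy(), q=q)
    comp["p_fdr"] = p_adj
    comp["significant"] = reject
    bfs = []
    for _, row in comp.iterrows():
        if row.significant:
            bfs.append(np.nan)
        else:
            bfs.append(
                dienes_bf(row.subj_mean, row.subj_sem, int(row.n_subjects)).bf
            )
    comp["bayes_factor"] = bfs
    comp = comp.drop(columns=["subj_mean", "subj_sem"])

    anova = perm_rm_anova(
        table, n_perm=anova_n_perm or min(n_perm, 2000), rng=rng
    )
    return StudyResults(comparisons=comp, anova=anova, n_perm=n_perm)


def enhancement_per_subject(
    table: pd.DataFrame, ref_condition: str, test_condition: str
) -> pd.Series:
    """Per-subject crossmodal enhancement in dB.

    Enhancement = mean over days and objects of (threshold under the
    reference condition - threshold under the test condition); positive
    means the test condition lowered the detection threshold.
    """
    for cond in (ref_condition, test_condition):
        if cond not in set(table["condition"]):
            raise ValueError(f"condition {cond!r} missing from table")
    wide = table.pivot_table(
        index=["subject_id", "day", "object"], columns="condition",
        values="threshold_db",
    )
    if wide[[ref_condition, test_condition]].isna().any().any():
        raise ValueError("both conditions must be present for every subject cell")
    diff = wide[ref_condition] - wide[test_condition]
    return diff.groupby("subject_id").mean()


def write_threshold_table(table: pd.DataFrame, path) -> None:
    table[TABLE_COLUMNS].to_csv(path, index=False)


def read_threshold_table(path) -> pd.DataFrame:
    """Read and validate a long-format threshold CSV."""
    table = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"threshold table missing columns: {sorted(missing)}")
    keys = table[["subject_id", "day", "object", "condition"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (subject, day, object, condition) keys")
    if not np.all(np.isfinite(table["threshold_db"])):
        raise ValueError("thresholds must be finite")
    return table
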