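"""YAML configuration for study designs and effect specifications.

Schema (all keys optional; omitted keys fall back to the package
defaults)::

    design:
      preset: study1 | study2_free_viewing | study2_dichoptic   # or explicit:
      n_subjects: 18
      n_days: 1
      objects: [triangle, tambourine]
      conditions: [fixation, onset_cue, object_video]
      method: staircase | psi
    effects:
      baseline_mu: {triangle: -16.0, tambourine: -10.0}
      between_subject_sd: 3.0
      within_subject_day_sd: 1.0
      condition_effects: {fixation: 0.0, object_video: -2.0, ...}
      beta: 2.0
      lapse: 0.02

A preset may be combined with overrides (e.g. ``preset: study1`` plus
``n_subjects: 30``).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Tuple

import yaml

from .experiment import EffectSpec, StudyDesign, study1_design, study2_design

__all__ = ["load_config", "design_from_dict", "effects_from_dict"]

_PRESETS = {
    "study1": study1_design,
    "study2_free_viewing": lambda: study2_design(condition_set="free_viewing"),
    "study2_dichoptic": lambda: study2_design(condition_set="dichoptic"),
}


def design_from_dict(cfg: dict) -> StudyDesign:
    cfg = dict(cfg or {})
    preset = cfg.pop("preset", "study1")
    if preset not in _PRESETS:
        raise ValueError(f"unknown design preset {preset!r}")
    design = _PRESETS[preset]()
    overrides = {}
    for key in ("n_subjects", "n_days", "method", "start_db"):
        if key in cfg:
            overrides[key] = cfg.pop(key)
    for key in ("objects", "conditions"):
        if key in cfg:
            overrides[key] = tuple(cfg.pop(key))
    if cfg:
        raise ValueError(f"unknown design keys: {sorted(cfg)}")
    return replace(design, **overrides) if overrides else design


def effects_from_dict(cfg: dict) -> EffectSpec:
    cfg = dict(cfg or {})
    effects = EffectSpec()
    if "baseline_mu" in cfg:
        effects.baseline_mu.update(cfg.pop("baseline_mu"))
    if "condition_effects" in cfg:
        effects.condition_effects.update(cfg.pop("condition_effects"))
    overrides = {}
    for key in ("between_subject_sd", "within_subject_day_sd", "beta", "lapse"):
        if key in cfg:
            overrides[key] = float(cfg.pop(key))
    if cfg:
        raise ValueError(f"unknown effects keys: {sorted(cfg)}")
    return replace(effects, **overrides) if overrides else effects


def load_config(path) -> Tuple[StudyDesign, EffectSpec]:
    """Load (design, effects) from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return design_from_dict(cfg.get("design", {})), effects_from_dict(
        cfg.get("effects", {})
    )
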