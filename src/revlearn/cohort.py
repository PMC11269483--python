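"""Synthetic cohorts with the VPVD study's structure and known ground truth.

A cohort mirrors the between-subjects design of the rat experiments:
three dose groups (vehicle / low / high), ~12 subjects per group, daily
sessions of up to 200 trials, a between-session reversal of the A/B
contingencies, and agents whose choices follow one of the nine RL
models with group-shifted parameters.

Subject-level parameters are drawn hierarchically: for each parameter a
group mean and SD on the transformed scale (logit for the rates and
rho, log for beta, identity for the stickiness weights), mapped back to
the natural bounds.  The effect presets encode the qualitative drug
effects reported for the two antagonists: the low 5-HT2A dose lowers
the punishment learning rate and reinforcement sensitivity and raises
both stickiness terms; the high dose lowers the punishment rate and
raises side stickiness; the 5-HT2C doses lower side stickiness, the
high dose also beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import MODELS, PARAM_TRANSFORMS, AgentParams, ModelSpec, simulate_agent
from .records import TrialRecord, records_to_frame
from .task import StimulusSet, apply_reversal, generate_session_schedule

__all__ = [
    "CohortConfig",
    "GroupEffect",
    "DEFAULT_GROUP_MEANS",
    "EFFECT_PRESETS",
    "preset_config",
    "sample_subject_params",
    "generate_cohort",
    "to_natural",
]

#: Baseline (vehicle) group means on the transformed scale.  Chosen as a
#: plausible vehicle profile for this task: moderate learning rates with
#: reward > punishment, beta ~ 4, mild positive stickiness, mild forgetting.
DEFAULT_GROUP_MEANS: dict[str, float] = {
    "alpha": -0.6,        # expit(-0.6) ~ 0.354
    "alpha_rew": -0.6,
    "alpha_pun": -1.0,    # expit(-1.0) ~ 0.269
    "beta": 1.4,          # exp(1.4)  ~ 4.06
    "kappa_side": 0.2,
    "kappa_stim": 0.3,
    "rho": 1.8,           # expit(1.8) ~ 0.858
}

#: Between-subject SD on the transformed scale, shared across parameters.
DEFAULT_GROUP_SD = 0.4


@dataclass(frozen=True)
class GroupEffect:
    """An additive shift of one group's mean for one parameter, applied on
    the transformed scale."""

    parameter: str
    group: str
    shift: float


#: Qualitative effect patterns of the two antagonists, as transformed-scale
#: shifts of the treated groups relative to vehicle.
EFFECT_PRESETS: dict[str, list[GroupEffect]] = {
    # 5-HT2A antagonist (M100907-like): low dose lowers alpha_pun and beta,
    # raises both stickiness terms; high dose lowers alpha_pun, raises kappa_side.
    "2a": [
        GroupEffect("alpha_pun", "low", -1.0),
        GroupEffect("beta", "low", -0.5),
        GroupEffect("kappa_side", "low", +0.5),
        GroupEffect("kappa_stim", "low", +0.4),
        GroupEffect("alpha_pun", "high", -0.8),
        GroupEffect("kappa_side", "high", +0.4),
    ],
    # 5-HT2C antagonist (SB-242084-like): both doses lower kappa_side,
    # the high dose also lowers beta.
    "2c": [
        GroupEffect("kappa_side", "low", -0.5),
        GroupEffect("kappa_side", "high", -0.4),
        GroupEffect("beta", "high", -0.5),
    ],
    "null": [],
}


@dataclass
class CohortConfig:
    """Study-design and generative settings for one synthetic experiment."""

    n_per_group: int = 12
    group_labels: tuple[str, ...] = ("vehicle", "low", "high")
    sessions_pre: int = 3
    sessions_post: int = 14
    max_trials: int = 200
    model: ModelSpec = field(default_factory=lambda: MODELS[9])
    group_means: dict[str, dict[str, float]] | None = None  # group -> param -> transformed mean
    group_sds: dict[str, dict[str, float]] | None = None
    effects: list[GroupEffect] = field(default_factory=list)
    seed: int = 0
    q_init: float = 0.5

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.sessions_post < 1:
            raise ValueError("at least one post-reversal session required")
        for e in self.effects:
            if e.parameter not in self.model.param_names:
                raise ValueError(
                    f"effect on {e.parameter!r} but model {self.model.model_id} "
                    f"has parameters {self.model.param_names}"
                )
            if e.group not in self.group_labels:
                raise ValueError(f"effect group {e.group!r} not in {self.group_labels}")

    def resolved_means(self) -> dict[str, dict[str, float]]:
        """Group means with defaults and effect shifts materialised."""
        if self.group_means is not None:
            base = {g: dict(self.group_means[g]) for g in self.group_labels}
        else:
            base = {
                g: {p: DEFAULT_GROUP_MEANS[p] for p in self.model.param_names}
                for g in self.group_labels
            }
        for e in self.effects:
            base[e.group][e.parameter] = base[e.group][e.parameter] + e.shift
        return base

    def resolved_sds(self) -> dict[str, dict[str, float]]:
        if self.group_sds is not None:
            return {g: dict(self.group_sds[g]) for g in self.group_labels}
        return {
            g: {p: DEFAULT_GROUP_SD for p in self.model.param_names}
            for g in self.group_labels
        }


def preset_config(name: str, **overrides) -> CohortConfig:
    """A ready-made cohort: ``"2a"`` (model-9 generator, 5-HT2A effect
    pattern), ``"2c"`` (model-7 generator, 5-HT2C pattern) or ``"null"``
    (model 9, no group differences)."""
    if name not in ("2a", "2c", "null"):
        raise ValueError(f"unknown preset {name!r}")
    model = MODELS[7] if name == "2c" else MODELS[9]
    return CohortConfig(model=model, effects=list(EFFECT_PRESETS[name]), **overrides)


def to_natural(param: str, x):
    """Map a transformed-scale value back to the parameter's natural scale."""
    kind = PARAM_TRANSFORMS[param]
    if kind == "logit":
        return expit(x)
    if kind == "log":
        return np.exp(x)
    return x


def sample_subject_params(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> tuple[AgentParams, dict[str, float]]:
    """Draw one subject's parameters from the group-level distributions.

    Returns the natural-scale :class:`AgentParams` and the raw
    transformed-scale draw (the ground truth the inference module is
    judged against).
    """
    if group not in config.group_labels:
        raise ValueError(f"unknown group {group!r}")
    means = config.resolved_means()[group]
    sds = config.resolved_sds()[group]
    raw = {p: means[p] + sds[p] * rng.standard_normal() for p in config.model.param_names}
    natural = {p: float(to_natural(p, v)) for p, v in raw.items()}
    return AgentParams.from_free(config.model, natural), raw


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full synthetic experiment.

    Returns ``(trials, truth)``: the trial log (one row per trial, all
    subjects) and the ground-truth table (one row per subject with the
    transformed- and natural-scale parameters and the group means used).
    Sessions ``1..sessions_pre`` use the acquisition contingencies;
    the reversal happens between sessions ``sessions_pre`` and
    ``sessions_pre + 1`` and values carry through it, so perseveration
    emerges naturally.
    """
    rng = np.random.default_rng(config.seed)
    base_set = StimulusSet()
    rev_set = apply_reversal(base_set)
    all_records: list[TrialRecord] = []
    truth_rows = []
    means = config.resolved_means()
    n_sessions = config.sessions_pre + config.sessions_post
    for g in config.group_labels:
        for i in range(config.n_per_group):
            sid = f"{g}_{i + 1:02d}"
            params, raw = sample_subject_params(config, g, rng)
            schedules = []
            for k in range(n_sessions):
                sset = base_set if k < config.sessions_pre else rev_set
                schedules.append(
                    generate_session_schedule(
                        config.max_trials, int(rng.integers(2**31)), sset
                    )
                )
            all_records.extend(
                simulate_agent(
                    schedules,
                    params,
                    config.model,
                    seed=int(rng.integers(2**31)),
                    subject_id=sid,
                    group_label=g,
                )
            )
            row = {"subject_id": sid, "group_label": g}
            for p in config.model.param_names:
                row[f"{p}_transformed"] = raw[p]
                row[p] = float(to_natural(p, raw[p]))
                row[f"{p}_group_mean_transformed"] = means[g][p]
            truth_rows.append(row)
    return records_to_frame(all_records), pd.DataFrame(truth_rows)
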