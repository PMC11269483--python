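"""The nine-member reinforcement-learning model family.

All nine models share a Rescorla–Wagner value update

    Q_{t+1}(c_t) = Q_t(c_t) + alpha * (r_t - Q_t(c_t))

with r_t in {0, 1}, and a softmax choice rule over the two presented
options whose logit for an option o on side s is

    beta * Q_t(o) + kappa_stim * 1[o == previous choice]
                  + kappa_side * 1[s == previous side]

The models differ in which parameters are free:

    1  alpha, beta
    2  alpha, beta, kappa_stim
    3  alpha, beta, kappa_side
    4  alpha, beta, kappa_side, kappa_stim
    5  alpha_rew, alpha_pun, beta
    6  alpha_rew, alpha_pun, beta, kappa_stim
    7  alpha_rew, alpha_pun, beta, kappa_side
    8  alpha_rew, alpha_pun, beta, kappa_side, kappa_stim
    9  alpha_rew, alpha_pun, beta, kappa_side, kappa_stim, rho

Split learning rates apply alpha_rew after reinforcement and alpha_pun
after non-reinforcement.  The discount factor rho (model 9 only) makes
the values of the *non-chosen* stimuli relax each trial: either toward
the initial value Q0 (``rho_mode="forget"``, the default, so rho = 1
means no forgetting) or toward zero (``rho_mode="decay"``).

Excluded parameters are pinned at neutral values (shared alpha, kappa =
0, rho = 1), so every model is an exact restriction of model 9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import TrialRecord
from .task import Side, SessionSchedule, StimulusSet, TrialSpec, reward_outcome

__all__ = [
    "ModelSpec",
    "MODELS",
    "AgentParams",
    "QState",
    "update_values",
    "choice_probability",
    "session_log_likelihood",
    "simulate_agent",
    "PARAM_TRANSFORMS",
]

#: transform linking each parameter's natural scale to the unconstrained
#: scale used by the hierarchy: logit for rates in [0,1], log for beta,
#: identity for the stickiness weights.
PARAM_TRANSFORMS = {
    "alpha": "logit",
    "alpha_rew": "logit",
    "alpha_pun": "logit",
    "beta": "log",
    "kappa_side": "identity",
    "kappa_stim": "identity",
    "rho": "logit",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters one member of the family includes."""

    model_id: int
    split_learning_rates: bool
    use_kappa_stim: bool
    use_kappa_side: bool
    use_rho: bool
    rho_mode: str = "forget"  # "forget" (toward Q0) or "decay" (toward 0)

    def __post_init__(self) -> None:
        if self.rho_mode not in ("forget", "decay"):
            raise ValueError("rho_mode must be 'forget' or 'decay'")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["alpha_rew", "alpha_pun"] if self.split_learning_rates else ["alpha"]
        names.append("beta")
        if self.use_kappa_side:
            names.append("kappa_side")
        if self.use_kappa_stim:
            names.append("kappa_stim")
        if self.use_rho:
            names.append("rho")
        return tuple(names)

    @property
    def label(self) -> str:
        """Human-readable parameter-set label (comparison-table column)."""
        pretty = {
            "alpha": "α", "alpha_rew": "α_rew", "alpha_pun": "α_pun",
            "beta": "β", "kappa_side": "κ_side", "kappa_stim": "κ_stim", "rho": "ρ",
        }
        return ", ".join(pretty[n] for n in self.param_names)


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, False, False, False, False),
    2: ModelSpec(2, False, True, False, False),
    3: ModelSpec(3, False, False, True, False),
    4: ModelSpec(4, False, True, True, False),
    5: ModelSpec(5, True, False, False, False),
    6: ModelSpec(6, True, True, False, False),
    7: ModelSpec(7, True, False, True, False),
    8: ModelSpec(8, True, True, True, False),
    9: ModelSpec(9, True, True, True, True),
}


@dataclass(frozen=True)
class AgentParams:
    """One subject's parameter vector on the natural scale."""

    alpha_rew: float
    alpha_pun: float
    beta: float
    kappa_side: float = 0.0
    kappa_stim: float = 0.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_rew <= 1.0 and 0.0 <= self.alpha_pun <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")

    @classmethod
    def from_free(cls, spec: ModelSpec, values: dict[str, float]) -> "AgentParams":
        """Build a full vector from a model's free parameters, pinning the
        excluded ones at neutral values."""
        extra = set(values) - set(spec.param_names)
        if extra:
            raise ValueError(f"parameters {sorted(extra)} not in model {spec.model_id}")
        missing = set(spec.param_names) - set(values)
        if missing:
            raise ValueError(f"missing parameters {sorted(missing)}")
        if spec.split_learning_rates:
            ar, ap = values["alpha_rew"], values["alpha_pun"]
        else:
            ar = ap = values["alpha"]
        return cls(
            alpha_rew=ar,
            alpha_pun=ap,
            beta=values["beta"],
            kappa_side=values.get("kappa_side", 0.0),
            kappa_stim=values.get("kappa_stim", 0.0),
            rho=values.get("rho", 1.0),
        )

    def as_vector(self) -> np.ndarray:
        """Fixed kernel order: [alpha_rew, alpha_pun, beta, kappa_side, kappa_stim, rho]."""
        return np.array(
            [self.alpha_rew, self.alpha_pun, self.beta, self.kappa_side, self.kappa_stim, self.rho]
        )


@dataclass
class QState:
    """Learned stimulus values plus the previous-trial choice memory."""

    q: dict[str, float]
    last_chosen_stim: str | None = None
    last_chosen_side: Side | None = None
    q_init: float = 0.5

    @classmethod
    def fresh(cls, stimulus_set: StimulusSet, q_init: float = 0.5) -> "QState":
        return cls(q={s: q_init for s in stimulus_set.stimuli}, q_init=q_init)

    def reset_memory(self) -> None:
        """Forget the previous choice (session boundary); values persist."""
        self.last_chosen_stim = None
        self.last_chosen_side = None

    def copy(self) -> "QState":
        return QState(dict(self.q), self.last_chosen_stim, self.last_chosen_side, self.q_init)


def update_values(
    state: QState,
    chosen_stim: str,
    reinforced: int,
    params: AgentParams,
    spec: ModelSpec,
) -> QState:
    """Rescorla–Wagner update of the chosen stimulus; rho-relaxation of the
    others (model 9).  Returns a new state; the input is not mutated."""
    if reinforced not in (0, 1):
        raise ValueError("reinforced must be 0 or 1")
    if chosen_stim not in state.q:
        raise KeyError(f"unknown stimulus {chosen_stim!r}")
    new = state.copy()
    alpha = params.alpha_rew if reinforced == 1 else params.alpha_pun
    new.q[chosen_stim] = state.q[chosen_stim] + alpha * (reinforced - state.q[chosen_stim])
    if spec.use_rho and params.rho != 1.0:
        target = state.q_init if spec.rho_mode == "forget" else 0.0
        for s in new.q:
            if s != chosen_stim:
                new.q[s] = params.rho * state.q[s] + (1.0 - params.rho) * target
    new.last_chosen_stim = chosen_stim
    new.last_chosen_side = None  # caller sets via record_choice when side known
    return new


def _logits(state: QState, trial: TrialSpec, params: AgentParams) -> tuple[float, float]:
    ll = params.beta * state.q[trial.left_stim]
    lr = params.beta * state.q[trial.right_stim]
    if state.last_chosen_stim is not None:
        if trial.left_stim == state.last_chosen_stim:
            ll += params.kappa_stim
        if trial.right_stim == state.last_chosen_stim:
            lr += params.kappa_stim
    if state.last_chosen_side is Side.L:
        ll += params.kappa_side
    elif state.last_chosen_side is Side.R:
        lr += params.kappa_side
    return ll, lr


def choice_probability(
    state: QState, trial: TrialSpec, params: AgentParams, spec: ModelSpec
) -> float:
    """Probability of choosing the left option (softmax in log space)."""
    ll, lr = _logits(state, trial, params)
    return float(np.exp(ll - np.logaddexp(ll, lr)))


def _check_sorted(records: list[TrialRecord]) -> None:
    prev = None
    for r in records:
        key = (r.session, r.trial_index)
        if prev is not None and key <= prev:
            raise ValueError(f"records not sorted: {key} after {prev}")
        prev = key


def session_log_likelihood(
    records: list[TrialRecord],
    params: AgentParams,
    spec: ModelSpec,
    carry_state: QState | None = None,
    stimulus_set: StimulusSet | None = None,
) -> tuple[float, QState]:
    """Log-likelihood (nats) of an observed trial sequence.

    This is the naive per-trial reference implementation: the compiled
    path in :mod:`revlearn.likelihood` must agree with it.  Q-values
    carry across session boundaries; the previous-choice memory resets
    whenever the session number changes.  The observed reinforcements
    are taken as ground truth, so the model never needs to know the
    reversal state.
    """
    _check_sorted(records)
    if carry_state is None:
        s = stimulus_set if stimulus_set is not None else StimulusSet()
        state = QState.fresh(s)
    else:
        state = carry_state.copy()
    ll = 0.0
    current_session = None
    for r in records:
        if r.session != current_session:
            state.reset_memory()
            current_session = r.session
        trial = TrialSpec(r.trial_index, r.trial_type, r.left_stim, r.right_stim)
        lL, lR = _logits(state, trial, params)
        lse = np.logaddexp(lL, lR)
        ll += (lL if r.chosen_side is Side.L else lR) - lse
        state = update_values(state, r.chosen_stim, r.reinforced, params, spec)
        state.last_chosen_side = r.chosen_side
    return float(ll), state


def simulate_agent(
    schedules: list[SessionSchedule],
    params: AgentParams,
    spec: ModelSpec,
    seed: int,
    subject_id: str = "s1",
    group_label: str = "vehicle",
    sessions_start: int = 1,
    carry_state: QState | None = None,
) -> list[TrialRecord]:
    """Simulate one agent through a list of session schedules.

    Choices are sampled from the softmax policy, outcomes from the task's
    reinforcement rule (each schedule's own stimulus set governs the
    current A/B roles, so between-session reversals are expressed by the
    schedules).  Values carry across sessions; choice memory resets at
    each session start.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    state = carry_state.copy() if carry_state is not None else QState.fresh(
        schedules[0].stimulus_set
    )
    records: list[TrialRecord] = []
    for k, sched in enumerate(schedules):
        state.reset_memory()
        session = sessions_start + k
        for trial in sched.trials:
            p_left = choice_probability(state, trial, params, spec)
            chose_left = rng.random() < p_left
            chosen = trial.left_stim if chose_left else trial.right_stim
            side = Side.L if chose_left else Side.R
            r = reward_outcome(trial, chosen, sched.stimulus_set, rng.random())
            records.append(
                TrialRecord(
                    subject_id=subject_id,
                    group_label=group_label,
                    session=session,
                    trial_index=trial.trial_index,
                    trial_type=trial.trial_type,
                    left_stim=trial.left_stim,
                    right_stim=trial.right_stim,
                    chosen_stim=chosen,
                    chosen_side=side,
                    reinforced=r,
                )
            )
            state = update_values(state, chosen, r, params, spec)
            state.last_chosen_side = side
    return records
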