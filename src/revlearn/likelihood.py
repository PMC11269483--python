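"""Compiled trial-loop likelihood kernels.

The hierarchical sampler evaluates the full-cohort likelihood tens of
thousands of times, so the sequential Q-update loop is JIT-compiled
with numba.  Trial logs are packed once into flat integer arrays
(:class:`PackedTrials`); the kernels then evaluate one subject, a whole
cohort, or a batch of parameter vectors (one per MCMC walker).

Kernel parameter order is fixed:
``[alpha_rew, alpha_pun, beta, kappa_side, kappa_stim, rho]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .task import StimulusSet

__all__ = ["PackedTrials", "pack_trials", "loglik_subject", "loglik_cohort", "loglik_walkers"]

RHO_FORGET = 0
RHO_DECAY = 1


@dataclass
class PackedTrials:
    """A cohort trial log flattened for the compiled kernels.

    Trials are concatenated per subject in (session, trial_index) order;
    ``offsets`` has length n_subjects + 1 and delimits each subject's
    slice.  Stimuli are coded 0/1/2 = A/B/C in `stimulus_set` order.
    """

    left: np.ndarray       # int8, stimulus code of the left option
    right: np.ndarray      # int8
    chose_left: np.ndarray  # int8 0/1
    reinforced: np.ndarray  # int8 0/1
    new_session: np.ndarray  # int8, 1 on the first trial of each session
    offsets: np.ndarray    # int64, per-subject slice bounds
    subjects: list[str]
    groups: list[str]      # per-subject group label
    q_init: float = 0.5

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_trials(self) -> int:
        return int(self.left.shape[0])


def pack_trials(
    df: pd.DataFrame, stimulus_set: StimulusSet | None = None, q_init: float = 0.5
) -> PackedTrials:
    s = stimulus_set if stimulus_set is not None else StimulusSet()
    code = {s.a_stim: 0, s.b_stim: 1, s.c_stim: 2}
    unknown = set(df["left_stim"]).union(df["right_stim"]) - set(code)
    if unknown:
        raise ValueError(f"stimuli {sorted(unknown)} not in stimulus set {s.stimuli}")
    df = df.sort_values(["subject_id", "session", "trial_index"], kind="mergesort")
    subjects = list(dict.fromkeys(df["subject_id"].astype(str)))
    group_of = dict(zip(df["subject_id"].astype(str), df["group_label"].astype(str)))
    left = df["left_stim"].map(code).to_numpy(np.int8)
    right = df["right_stim"].map(code).to_numpy(np.int8)
    chose_left = (df["chosen_side"] == "L").to_numpy(np.int8)
    reinforced = df["reinforced"].to_numpy(np.int8)
    sid = df["subject_id"].astype(str).to_numpy()
    sess = df["session"].to_numpy()
    new_session = np.ones(len(df), dtype=np.int8)
    same = (sid[1:] == sid[:-1]) & (sess[1:] == sess[:-1])
    new_session[1:] = (~same).astype(np.int8)
    counts = df.groupby("subject_id", sort=False).size().reindex(subjects).to_numpy()
    offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return PackedTrials(
        left=left,
        right=right,
        chose_left=chose_left,
        reinforced=reinforced,
        new_session=new_session,
        offsets=offsets,
        subjects=subjects,
        groups=[group_of[u] for u in subjects],
        q_init=q_init,
    )


@njit(cache=True)
def _loglik_slice(left, right, chose_left, reinforced, new_session, lo, hi, p, q_init, rho_mode):
    q = np.empty(3)
    for k in range(3):
        q[k] = q_init
    last_stim = -1
    last_side = -1
    ll = 0.0
    for t in range(lo, hi):
        if new_session[t] == 1:
            last_stim = -1
            last_side = -1
        lL = p[2] * q[left[t]]
        lR = p[2] * q[right[t]]
        if left[t] == last_stim:
            lL += p[4]
        if right[t] == last_stim:
            lR += p[4]
        if last_side == 0:
            lL += p[3]
        elif last_side == 1:
            lR += p[3]
        m = lL if lL > lR else lR
        lse = m + np.log(np.exp(lL - m) + np.exp(lR - m))
        if chose_left[t] == 1:
            ll += lL - lse
            c = left[t]
            last_side = 0
        else:
            ll += lR - lse
            c = right[t]
            last_side = 1
        a = p[0] if reinforced[t] == 1 else p[1]
        q[c] = q[c] + a * (reinforced[t] - q[c])
        if p[5] != 1.0:
            target = q_init if rho_mode == RHO_FORGET else 0.0
            for k in range(3):
                if k != c:
                    q[k] = p[5] * q[k] + (1.0 - p[5]) * target
        last_stim = c
    return ll


@njit(cache=True)
def _loglik_cohort(left, right, chose_left, reinforced, new_session, offsets, P, q_init, rho_mode):
    n_sub = offsets.shape[0] - 1
    out = np.empty(n_sub)
    for s in range(n_sub):
        out[s] = _loglik_slice(
            left, right, chose_left, reinforced, new_session,
            offsets[s], offsets[s + 1], P[s], q_init, rho_mode,
        )
    return out


@njit(cache=True)
def _loglik_walkers(left, right, chose_left, reinforced, new_session, offsets, P, q_init, rho_mode):
    n_w = P.shape[0]
    n_sub = offsets.shape[0] - 1
    out = np.zeros(n_w)
    for w in range(n_w):
        for s in range(n_sub):
            out[w] += _loglik_slice(
                left, right, chose_left, reinforced, new_session,
                offsets[s], offsets[s + 1], P[w, s], q_init, rho_mode,
            )
    return out


def _rho_mode_code(rho_mode: str) -> int:
    return RHO_FORGET if rho_mode == "forget" else RHO_DECAY


def loglik_subject(packed: PackedTrials, subject_idx: int, p: np.ndarray, rho_mode: str = "forget") -> float:
    """Log-likelihood of one subject's trials for one parameter vector."""
    return float(
        _loglik_slice(
            packed.left, packed.right, packed.chose_left, packed.reinforced,
            packed.new_session, packed.offsets[subject_idx], packed.offsets[subject_idx + 1],
            np.asarray(p, dtype=np.float64), packed.q_init, _rho_mode_code(rho_mode),
        )
    )


def loglik_cohort(packed: PackedTrials, P: np.ndarray, rho_mode: str = "forget") -> np.ndarray:
    """Per-subject log-likelihoods; ``P`` has shape (n_subjects, 6)."""
    return _loglik_cohort(
        packed.left, packed.right, packed.chose_left, packed.reinforced,
        packed.new_session, packed.offsets, np.asarray(P, dtype=np.float64),
        packed.q_init, _rho_mode_code(rho_mode),
    )


def loglik_walkers(packed: PackedTrials, P: np.ndarray, rho_mode: str = "forget") -> np.ndarray:
    """Total cohort log-likelihood per walker; ``P`` has shape (n_walkers, n_subjects, 6)."""
    return _loglik_walkers(
        packed.left, packed.right, packed.chose_left, packed.reinforced,
        packed.new_session, packed.offsets, np.asarray(P, dtype=np.float64),
        packed.q_init, _rho_mode_code(rho_mode),
    )
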