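"""Conventional behavioural analysis of VPVD trial logs.

Post-reversal standard-trial outcomes are coded into three ordered
phases — perseverative, random, learning — by rolling 30-trial windows
tested against chance with one-tailed binomial cutoffs (<=10/30 below
chance, >=20/30 above chance at alpha = 0.05, p = 0.5).  Errors are
counted up to and including the first disjoint 30-trial block reaching
the 24/30 criterion.  Session-level accuracy uses percent correct on
standard trials and percent optimal choice on the two probe types;
win-stay/lose-shift summarises outcome-dependent choice repetition.
Probe trials are excluded from phase coding and errors-to-criterion;
sessions within the reversal are concatenated in order.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import StimulusSet, TrialType, apply_reversal

__all__ = [
    "PhaseLabel",
    "MetricsTable",
    "binomial_cutoffs",
    "label_phases",
    "errors_to_criterion",
    "errors_per_phase",
    "percent_measures",
    "win_stay_lose_shift",
    "conventional_metrics",
    "post_reversal_standard_outcomes",
]


class PhaseLabel(enum.IntEnum):
    """Ordered reversal phases; the order is monotone within a subject."""

    PERSEVERATIVE = 0
    RANDOM = 1
    LEARNING = 2


def binomial_cutoffs(window: int = 30, alpha: float = 0.05, p: float = 0.5) -> tuple[int, int]:
    """One-tailed binomial cutoffs (lower, upper) for a window of trials.

    ``k <= lower`` is significantly below chance and ``k >= upper``
    significantly above.  For window=30, alpha=0.05: (10, 20).
    """
    ks = np.arange(window + 1)
    cdf = stats.binom.cdf(ks, window, p)
    sf = stats.binom.sf(ks - 1, window, p)  # P(X >= k)
    lower = int(ks[cdf < alpha].max()) if np.any(cdf < alpha) else -1
    upper = int(ks[sf < alpha].min()) if np.any(sf < alpha) else window + 1
    return lower, upper


def _window_class(count: int, lower: int, upper: int) -> PhaseLabel:
    if count <= lower:
        return PhaseLabel.PERSEVERATIVE
    if count >= upper:
        return PhaseLabel.LEARNING
    return PhaseLabel.RANDOM


def label_phases(
    correct, window: int = 30, alpha: float = 0.05
) -> tuple[list[PhaseLabel], dict[PhaseLabel, int]]:
    """Phase-code a post-reversal binary outcome sequence.

    Each trial t >= window is classified by the window ending at it,
    clamped so phases never regress (once random/learning has begun,
    later below-chance windows do not re-open perseveration).  Trials
    before the first complete window inherit its label.  Sequences
    shorter than the window are labelled RANDOM with a warning.

    Returns the per-trial labels and the 0-based start index of each
    non-empty phase.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(list(correct), dtype=int)
    if not np.isin(x, [0, 1]).all():
        raise ValueError("outcomes must be binary")
    n = x.size
    if n < window:
        warnings.warn(
            f"sequence of {n} trials shorter than window {window}; labelling RANDOM",
            stacklevel=2,
        )
        return [PhaseLabel.RANDOM] * n, ({PhaseLabel.RANDOM: 0} if n else {})
    lower, upper = binomial_cutoffs(window, alpha)
    counts = np.convolve(x, np.ones(window, dtype=int), mode="valid")  # ends at t = window-1..n-1
    labels: list[PhaseLabel] = []
    phase = _window_class(int(counts[0]), lower, upper)
    labels.extend([phase] * (window - 1))
    for c in counts:
        phase = max(phase, _window_class(int(c), lower, upper))
        labels.append(phase)
    boundaries: dict[PhaseLabel, int] = {}
    for i, lab in enumerate(labels):
        if lab not in boundaries:
            boundaries[lab] = i
    return labels, boundaries


def errors_to_criterion(
    correct, criterion: tuple[int, int] = (24, 30)
) -> tuple[int, bool, int | None]:
    """Errors from reversal up to and including the first disjoint
    ``criterion[1]``-trial block with >= ``criterion[0]`` correct.

    Returns ``(errors, reached, end_index)`` where ``end_index`` is the
    0-based index of the last trial of the qualifying block (None when
    the criterion is never reached, in which case errors are counted
    over the whole sequence).
    """
    need, block = criterion
    x = np.asarray(list(correct), dtype=int)
    for b in range(x.size // block):
        seg = x[b * block : (b + 1) * block]
        if seg.sum() >= need:
            end = (b + 1) * block - 1
            return int((1 - x[: end + 1]).sum()), True, end
    return int((1 - x).sum()), False, None


def errors_per_phase(
    correct,
    window: int = 30,
    alpha: float = 0.05,
    criterion: tuple[int, int] = (24, 30),
) -> dict[PhaseLabel, int]:
    """Pre-criterion errors split by phase.

    The sequence is truncated at the criterion point (as in the
    standard analysis), phase-coded, and errors counted per label; the
    counts therefore sum to the total pre-criterion errors.
    """
    x = np.asarray(list(correct), dtype=int)
    _, reached, end = errors_to_criterion(x, criterion)
    seg = x[: end + 1] if reached else x
    labels, _ = label_phases(seg, window, alpha) if seg.size else ([], {})
    out = {p: 0 for p in PhaseLabel}
    for xi, lab in zip(seg, labels):
        if xi == 0:
            out[lab] += 1
    return out


def _current_roles(stimulus_set: StimulusSet, session: int, reversal_session: int):
    s = apply_reversal(stimulus_set) if session >= reversal_session else stimulus_set
    return s.current_a, s.current_b, s.c_stim


def percent_measures(
    df: pd.DataFrame, stimulus_set: StimulusSet, reversal_session: int
) -> pd.DataFrame:
    """Per subject x session percent correct (standard trials) and percent
    optimal choice (positive and negative probes).

    ``reversal_session`` is the first session run under reversed
    contingencies; ``stimulus_set`` describes the pre-reversal roles.
    Cells with no trials of a type are missing, not zero.
    """
    rows = []
    for (sid, sess), g in df.groupby(["subject_id", "session"], sort=True):
        a_cur, _, c = _current_roles(stimulus_set, int(sess), reversal_session)
        std = g[g["trial_type"] == TrialType.STANDARD.value]
        pos = g[g["trial_type"] == TrialType.POS_PROBE.value]
        neg = g[g["trial_type"] == TrialType.NEG_PROBE.value]
        rows.append(
            {
                "subject_id": sid,
                "group_label": g["group_label"].iloc[0],
                "session": int(sess),
                "pct_correct_standard": 100.0 * (std["chosen_stim"] == a_cur).mean()
                if len(std)
                else np.nan,
                "pct_optimal_pos_probe": 100.0 * (pos["chosen_stim"] == a_cur).mean()
                if len(pos)
                else np.nan,
                "pct_optimal_neg_probe": 100.0 * (neg["chosen_stim"] == c).mean()
                if len(neg)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def win_stay_lose_shift(df: pd.DataFrame) -> pd.DataFrame:
    """Per-subject win-stay and lose-shift proportions.

    Pairs are consecutive trials within one session where the previously
    chosen stimulus is available again; win-stay is the probability of
    repeating it after reinforcement, lose-shift of abandoning it after
    non-reinforcement.  Missing when a subject has no eligible pairs.
    """
    rows = []
    for sid, g in df.groupby("subject_id", sort=True):
        wins = stays_after_win = losses = shifts_after_loss = 0
        for _, sess in g.groupby("session", sort=True):
            sess = sess.sort_values("trial_index")
            prev_chosen = prev_reinf = None
            for row in sess.itertuples(index=False):
                if prev_chosen is not None and prev_chosen in (row.left_stim, row.right_stim):
                    repeat = row.chosen_stim == prev_chosen
                    if prev_reinf == 1:
                        wins += 1
                        stays_after_win += repeat
                    else:
                        losses += 1
                        shifts_after_loss += not repeat
                prev_chosen, prev_reinf = row.chosen_stim, row.reinforced
        rows.append(
            {
                "subject_id": sid,
                "group_label": g["group_label"].iloc[0],
                "win_stay": stays_after_win / wins if wins else np.nan,
                "lose_shift": shifts_after_loss / losses if losses else np.nan,
                "n_win_pairs": wins,
                "n_loss_pairs": losses,
            }
        )
    return pd.DataFrame(rows)


def post_reversal_standard_outcomes(
    df: pd.DataFrame, stimulus_set: StimulusSet, reversal_session: int
) -> dict[str, np.ndarray]:
    """Per-subject binary correct/incorrect sequence over post-reversal
    standard trials, sessions concatenated in order."""
    rev = apply_reversal(stimulus_set)
    a_cur = rev.current_a
    sub = df[
        (df["session"] >= reversal_session)
        & (df["trial_type"] == TrialType.STANDARD.value)
    ].sort_values(["subject_id", "session", "trial_index"], kind="mergesort")
    return {
        str(sid): (g["chosen_stim"] == a_cur).to_numpy(int)
        for sid, g in sub.groupby("subject_id", sort=True)
    }


@dataclass
class MetricsTable:
    """Conventional metrics: session-level percentages and subject-level
    reversal measures."""

    per_session: pd.DataFrame
    per_subject: pd.DataFrame


def conventional_metrics(
    df: pd.DataFrame,
    stimulus_set: StimulusSet,
    reversal_session: int,
    window: int = 30,
    alpha: float = 0.05,
    criterion: tuple[int, int] = (24, 30),
) -> MetricsTable:
    """Full conventional analysis of a trial log."""
    per_session = percent_measures(df, stimulus_set, reversal_session)
    wsls = win_stay_lose_shift(df)
    seqs = post_reversal_standard_outcomes(df, stimulus_set, reversal_session)
    rows = []
    for sid, seq in seqs.items():
        errs, reached, _ = errors_to_criterion(seq, criterion)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_phase = errors_per_phase(seq, window, alpha, criterion)
        rows.append(
            {
                "subject_id": sid,
                "errors_to_criterion": errs,
                "criterion_reached": reached,
                "errors_perseverative": per_phase[PhaseLabel.PERSEVERATIVE],
                "errors_random": per_phase[PhaseLabel.RANDOM],
                "errors_learning": per_phase[PhaseLabel.LEARNING],
            }
        )
    per_subject = wsls.merge(pd.DataFrame(rows), on="subject_id", how="left")
    return MetricsTable(per_session=per_session, per_subject=per_subject)
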