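"""Valence-probe visual discrimination (VPVD) task structure.

The VPVD task presents three visual stimuli: A is reinforced on every
trial it is chosen, B is never reinforced, and a probe stimulus C is
reinforced with probability 0.5.  Standard trials pair A with B; probe
trials pair C with either A (positive probe) or B (negative probe).
Each disjoint 8-trial bin of a session contains exactly one probe of
each type, never on the first trial of the bin.  After acquisition the
A/B contingencies are reversed between sessions; C is unaffected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrialType",
    "Side",
    "StimulusSet",
    "TrialSpec",
    "SessionSchedule",
    "generate_session_schedule",
    "validate_schedule",
    "reward_outcome",
    "apply_reversal",
    "PROBE_BIN_SIZE",
]

PROBE_BIN_SIZE = 8


class TrialType(str, enum.Enum):
    STANDARD = "STANDARD"
    POS_PROBE = "POS_PROBE"
    NEG_PROBE = "NEG_PROBE"


class Side(str, enum.Enum):
    L = "L"
    R = "R"


@dataclass(frozen=True)
class StimulusSet:
    """The three task stimuli and the current reversal state.

    ``a_stim`` is the fully reinforced stimulus and ``b_stim`` the never
    reinforced one *before* reversal; when ``reversed_flag`` is set their
    roles swap.  ``c_stim`` is the 50% probe stimulus and never changes
    role.
    """

    a_stim: str = "A"
    b_stim: str = "B"
    c_stim: str = "C"
    reversed_flag: bool = False

    def __post_init__(self) -> None:
        if len({self.a_stim, self.b_stim, self.c_stim}) != 3:
            raise ValueError("stimulus identifiers must be distinct")

    @property
    def current_a(self) -> str:
        """Stimulus currently reinforced 100% of the time."""
        return self.b_stim if self.reversed_flag else self.a_stim

    @property
    def current_b(self) -> str:
        """Stimulus currently never reinforced."""
        return self.a_stim if self.reversed_flag else self.b_stim

    @property
    def stimuli(self) -> tuple[str, str, str]:
        return (self.a_stim, self.b_stim, self.c_stim)


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int  # 1-based within session
    trial_type: TrialType
    left_stim: str
    right_stim: str

    def __post_init__(self) -> None:
        if self.left_stim == self.right_stim:
            raise ValueError("left and right stimuli must differ")

    @property
    def stimuli(self) -> frozenset[str]:
        return frozenset((self.left_stim, self.right_stim))


@dataclass
class SessionSchedule:
    trials: list[TrialSpec]
    max_trials: int
    rng_seed: int
    stimulus_set: StimulusSet = field(default_factory=StimulusSet)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def apply_reversal(stimulus_set: StimulusSet) -> StimulusSet:
    """Swap the reinforcement roles of A and B (an involution); C unchanged."""
    return replace(stimulus_set, reversed_flag=not stimulus_set.reversed_flag)


def _expected_pair(trial_type: TrialType, s: StimulusSet) -> frozenset[str]:
    # Probe pairings follow the *current* valence: the positive probe pairs C
    # with whichever stimulus is currently fully reinforced.
    if trial_type is TrialType.STANDARD:
        return frozenset((s.a_stim, s.b_stim))
    if trial_type is TrialType.POS_PROBE:
        return frozenset((s.current_a, s.c_stim))
    return frozenset((s.current_b, s.c_stim))


def generate_session_schedule(
    max_trials: int,
    seed: int,
    stimulus_set: StimulusSet | None = None,
    bin_size: int = PROBE_BIN_SIZE,
) -> SessionSchedule:
    """Generate one session's trial schedule.

    Each complete ``bin_size``-trial bin contains exactly one positive and
    one negative probe, at distinct uniformly chosen positions 2..bin_size;
    remaining trials are standard.  A trailing partial bin is all-standard.
    The left/right placement of the two stimuli on every trial is an
    independent fair coin.  Deterministic for a fixed seed.
    """
    if max_trials < bin_size:
        raise ValueError(
            f"max_trials must be at least {bin_size} (one full probe bin); got {max_trials}"
        )
    s = stimulus_set if stimulus_set is not None else StimulusSet()
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    n_full_bins = max_trials // bin_size
    for b in range(n_full_bins):
        # probe positions within the bin: 1-based 2..bin_size, no replacement
        pos, neg = rng.choice(np.arange(2, bin_size + 1), size=2, replace=False)
        for j in range(1, bin_size + 1):
            idx = b * bin_size + j
            if j == pos:
                ttype = TrialType.POS_PROBE
                pair = (s.current_a, s.c_stim)
            elif j == neg:
                ttype = TrialType.NEG_PROBE
                pair = (s.current_b, s.c_stim)
            else:
                ttype = TrialType.STANDARD
                pair = (s.a_stim, s.b_stim)
            if rng.random() < 0.5:
                pair = (pair[1], pair[0])
            trials.append(TrialSpec(idx, ttype, pair[0], pair[1]))
    for idx in range(n_full_bins * bin_size + 1, max_trials + 1):
        pair = (s.a_stim, s.b_stim)
        if rng.random() < 0.5:
            pair = (pair[1], pair[0])
        trials.append(TrialSpec(idx, TrialType.STANDARD, pair[0], pair[1]))
    return SessionSchedule(trials=trials, max_trials=max_trials, rng_seed=seed, stimulus_set=s)


def validate_schedule(schedule: SessionSchedule, bin_size: int = PROBE_BIN_SIZE) -> None:
    """Independent re-check of the schedule invariants; raises on violation.

    Checks: length, contiguous 1-based indices, correct stimulus pairings
    per trial type, exactly one probe of each type per complete bin, probes
    never first-in-bin, trailing partial bin all-standard.
    """
    s = schedule.stimulus_set
    if len(schedule.trials) > schedule.max_trials:
        raise ValueError("schedule longer than max_trials")
    for i, t in enumerate(schedule.trials, start=1):
        if t.trial_index != i:
            raise ValueError(f"trial_index {t.trial_index} at position {i}")
        if t.stimuli != _expected_pair(t.trial_type, s):
            raise ValueError(f"trial {i}: stimuli {t.stimuli} wrong for {t.trial_type}")
    n = len(schedule.trials)
    for b in range(n // bin_size):
        bin_trials = schedule.trials[b * bin_size : (b + 1) * bin_size]
        types = [t.trial_type for t in bin_trials]
        if types.count(TrialType.POS_PROBE) != 1 or types.count(TrialType.NEG_PROBE) != 1:
            raise ValueError(f"bin {b}: probe counts {types}")
        if types[0] is not TrialType.STANDARD:
            raise ValueError(f"bin {b}: probe on first trial of bin")
    for t in schedule.trials[(n // bin_size) * bin_size :]:
        if t.trial_type is not TrialType.STANDARD:
            raise ValueError("probe trial in trailing partial bin")


def reward_outcome(
    trial: TrialSpec, chosen_stim: str, stimulus_set: StimulusSet, u: float
) -> int:
    """Reinforcement for choosing ``chosen_stim`` on ``trial``.

    The currently valid A is always reinforced, the current B never, and
    C is reinforced iff the uniform draw ``u`` < 0.5.
    """
    if chosen_stim not in trial.stimuli:
        raise ValueError(f"chosen stimulus {chosen_stim!r} not presented on trial {trial.trial_index}")
    if chosen_stim == stimulus_set.current_a:
        return 1
    if chosen_stim == stimulus_set.current_b:
        return 0
    return int(u < 0.5)
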