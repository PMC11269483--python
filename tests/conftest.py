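import numpy as np
import pytest

import revlearn as rl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def model9():
    return rl.MODELS[9]


@pytest.fixture
def params9():
    return rl.AgentParams.from_free(
        rl.MODELS[9],
        dict(alpha_rew=0.4, alpha_pun=0.3, beta=4.0, kappa_side=0.2, kappa_stim=0.3, rho=0.9),
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 3-group cohort with injected effects: 2 subjects/group,
    1 pre + 2 post sessions of 40 trials."""
    cfg = rl.preset_config("2a", n_per_group=2, sessions_pre=1, sessions_post=2,
                           max_trials=40, seed=99)
    trials, truth = rl.generate_cohort(cfg)
    return cfg, trials, truth


def random_session_records(rng, n_trials=40, subject="s1", session=1, group="vehicle"):
    """Random but internally consistent trial records for likelihood tests."""
    sset = rl.StimulusSet()
    sched = rl.generate_session_schedule(
        max(8, (n_trials // 8) * 8), int(rng.integers(2**31)), sset
    )
    records = []
    for t in sched.trials[:n_trials]:
        chose_left = rng.random() < 0.5
        chosen = t.left_stim if chose_left else t.right_stim
        side = rl.Side.L if chose_left else rl.Side.R
        r = rl.reward_outcome(t, chosen, sset, rng.random())
        records.append(
            rl.TrialRecord(subject, group, session, t.trial_index, t.trial_type,
                           t.left_stim, t.right_stim, chosen, side, r)
        )
    return records
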