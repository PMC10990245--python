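import numpy as np
import pandas as pd
import pytest

from volbandit.hierarchy import build_model, sample_posterior
from volbandit.models import ModelSpec, simulate_choices
from volbandit.studies import recovery_population, sample_population
from volbandit.task import generate_participants, learning_phase


def make_trials(env_seq, choices=None, rewards=None, winning=None, block=None):
    """Hand-build a trial table from short sequences."""
    n = len(env_seq)
    block = block if block is not None else [0] * n
    within = {}
    wct = []
    for e, b in zip(env_seq, block):
        key = (b, e)
        wct.append(within.get(key, 0))
        within[key] = wct[-1] + 1
    return pd.DataFrame(
        {
            "participant_id": 0,
            "phase": "learning",
            "block": block,
            "trial": np.arange(n),
            "environment": env_seq,
            "within_casino_trial": wct,
            "correct_machine": 0,
            "winning_machine": winning if winning is not None else [0] * n,
            "choice": choices if choices is not None else [np.nan] * n,
            "reward": rewards if rewards is not None else [np.nan] * n,
        }
    )


@pytest.fixture(scope="session")
def dual_dataset():
    """Small dataset simulated from the env-specific dual model."""
    rng = np.random.default_rng(2024)
    spec = ModelSpec(True, "dual")
    means, sds = recovery_population(spec)
    pop = sample_population(spec, means, sds, 8, rng)
    data = generate_participants(learning_phase(2, 120, stable_p=0.75), 8, rng)
    return simulate_choices(data, spec, pop, rng), spec, pop


@pytest.fixture(scope="session")
def dual_fit(dual_dataset):
    """One short hierarchical fit of the generating model, reused by tests."""
    data, spec, _pop = dual_dataset
    model = build_model(data, spec)
    post = sample_posterior(
        model, n_chains=2, n_iter=500, n_burn_in=220, seed=99, traj_len=1.6
    )
    return post, data
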