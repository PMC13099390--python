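import numpy as np
import pandas as pd
import pytest

from delaydisc.items import kirby_mcq
from delaydisc.synthetic import simulate_agent_trials


@pytest.fixture(scope="session")
def bank():
    return kirby_mcq()


@pytest.fixture(scope="session")
def mcq_trials_factory():
    """Simulated MCQ(+adaptive) trials for a softmax agent."""

    def make(log_k, log_beta, seed=0, participant_id="sim", timepoint="MA1",
             include_adaptive=True):
        return simulate_agent_trials(
            log_k, log_beta, seed, participant_id=participant_id,
            timepoint=timepoint, include_adaptive=include_adaptive,
        )

    return make


@pytest.fixture(scope="session")
def small_population(mcq_trials_factory):
    """30 simulated participants (MCQ + adaptive) with known parameters."""
    rng = np.random.default_rng(11)
    frames, truth = [], {}
    for i in range(30):
        pid = f"S{i:03d}"
        lk = -4.5 + 1.0 * rng.standard_normal()
        lb = -1.0 + 0.5 * rng.standard_normal()
        truth[pid] = (lk, lb)
        frames.append(
            mcq_trials_factory(lk, lb, seed=500 + i, participant_id=pid)
        )
    return pd.concat(frames, ignore_index=True), truth
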