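"""Shared simulation fixtures.

The heavier behavioral checks (reversal learning, gating protection,
phase-amplitude coupling, stability ordering) all consume the same
replicated simulations, so those are run once per session here.
"""

import numpy as np
import pytest

from syncgate import experiment, tasks

N_RW_REPS = 5
N_BP_REPS = 3
BP_TRIALS = 1200


@pytest.fixture(scope="session")
def rw_full_runs():
    """Five replications of the full linear model on the 360-trial task,
    with dense traces and per-module weight-change bookkeeping."""
    return [
        experiment.run_simulation(
            "rw-full", tasks.make_one_dim_task(rep), beta=0.2, seed=rep,
            record_traces=True, record_weight_change=True)
        for rep in range(N_RW_REPS)
    ]


@pytest.fixture(scope="session")
def bp_pair_runs():
    """Paired full/no-synchrony multi-layer runs on a shortened (1200-trial)
    three-dimensional task, three replications."""
    pairs = []
    for rep in range(N_BP_REPS):
        task = tasks.make_multi_dim_task(3, rep, n_trials=BP_TRIALS)
        pairs.append((
            experiment.run_simulation("bp-full", task, beta=0.2, seed=rep),
            experiment.run_simulation("bp-nosync", task, beta=0.2, seed=rep),
        ))
    return pairs
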