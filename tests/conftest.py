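"""Shared fixtures.

The canonical 3BFF pipeline (task-train a GRU to criterion, simulate
spiking) is expensive, so it is built once per session and shared by the
task-training invariant tests and the end-to-end acceptance tests.
Problem sizes here are desk scale: 80-step trials, 300 trials, 40
neurons.
"""

import pytest

from ctdbench.experiments import build_3bff_dataset


@pytest.fixture(scope="session")
def canonical_3bff():
    """(dataset, tt_model, trial_batch) for the 3-bit flip-flop task."""
    return build_3bff_dataset(seed=0, n_trials=300, trial_len=80,
                              n_neurons=40)
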