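import numpy as np
import pytest

from tvgc import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_session():
    """A small two-group session shared by pipeline-level tests."""
    graphs = synth.make_group_graphs(n_channels=7, n_edges=7, seed=5)
    design = synth.SessionDesign(
        groups=graphs,
        n_subjects_per_group=3,
        n_trials=10,
        trial_duration=4.0,
        seed=7,
    )
    return synth.simulate_session(design)
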