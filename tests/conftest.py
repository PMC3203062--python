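import numpy as np
import pytest

from sailnet.dynamics import run_inference
from sailnet.presets import toy_probe_patches, train_toy_network


@pytest.fixture(scope="session")
def toy_run():
    """One converged desk-scale training run shared across the suite."""
    return train_toy_network(seed=1)


@pytest.fixture(scope="session")
def toy_probe(toy_run):
    """Probe patches and responses of the converged toy network."""
    patches = toy_probe_patches(seed=1, n=10_000)
    responses = [run_inference(toy_run.params, p, toy_run.dynamics) for p in patches]
    return patches, responses


@pytest.fixture(scope="session")
def toy_probe_counts(toy_probe):
    _, responses = toy_probe
    return np.stack([r.counts for r in responses])
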