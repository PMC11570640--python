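import numpy as np
import pytest

import moodgraph as mg
from moodgraph import synthetic


@pytest.fixture(scope="session")
def montage16():
    return mg.generate_montage(16)


@pytest.fixture(scope="session")
def default_fixture():
    """Full default-layout dataset (22+29 subjects x 29 segments), seed 17."""
    samples, manifest = mg.generate_dataset(mg.FixtureConfig(seed=17))
    data = mg.as_arrays(samples)
    data["eeg_adjacency"] = synthetic.default_eeg_adjacency(
        data["eeg"].shape[1])
    return {"samples": samples, "manifest": manifest, "data": data}


@pytest.fixture(scope="session")
def tiny_fixture():
    """Desk-scale dataset for fast training tests."""
    cfg = mg.FixtureConfig(n_mdd_subjects=5, n_hc_subjects=5,
                           segments_per_subject=6, n_eeg_channels=16,
                           n_audio_slices=8, seed=3)
    samples, manifest = mg.generate_dataset(cfg)
    data = mg.as_arrays(samples)
    data["eeg_adjacency"] = synthetic.default_eeg_adjacency(16)
    return {"samples": samples, "manifest": manifest, "data": data,
            "config": cfg}


def random_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric binary adjacency containing a spanning chain."""
    a = (rng.random((n, n)) < 0.4).astype(float)
    a = np.triu(a, 1)
    for i in range(n - 1):
        a[i, i + 1] = 1.0
    return a + a.T
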