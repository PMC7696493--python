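import numpy as np
import pytest

from cyclephase.features import LabeledDataset, extract
from cyclephase.sim import SimConfig, generate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """Two noise-free riding cycles."""
    return generate_recording(
        SimConfig(n_cycles=2, vibration_snr_db=np.inf, seed=1)
    )


@pytest.fixture(scope="session")
def noisy_recording():
    """Ten cycles at 10 dB vibration SNR."""
    return generate_recording(SimConfig(n_cycles=10, vibration_snr_db=10.0, seed=3))


@pytest.fixture(scope="session")
def dataset(noisy_recording):
    return extract(noisy_recording)


@pytest.fixture(scope="session")
def toy_clusters():
    """Four well-separated Gaussian blobs, one per phase (linearly separable)."""
    rng = np.random.default_rng(11)
    centers = {1: (0, 0), 2: (8, 0), 3: (0, 8), 4: (8, 8)}
    X, y = [], []
    for phase, (cx, cy) in centers.items():
        pts = rng.normal(size=(30, 2)) * 0.3 + [cx, cy]
        # pad to the 5-D feature layout; the trailing dims are uninformative
        X.append(np.column_stack([pts, np.zeros((30, 3))]))
        y.extend([phase] * 30)
    return LabeledDataset(X=np.vstack(X), y=np.array(y))
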