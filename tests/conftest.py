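import numpy as np
import pytest

from imspeech.synthetic import SimulationConfig, generate_dataset, generate_tone_mixture


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_tone_channel():
    """One noiseless 5 Hz + 50 Hz channel, 2.048 s at 250 Hz."""
    rec, params = generate_tone_mixture([5.0, 50.0], [1.0, 1.0], 2.048, 250.0, 1)
    return rec.data[0], params


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small balanced dataset: 1 participant, 3 channels, 2 classes."""
    cfg = SimulationConfig(
        n_participants=1, n_channels=3, trial_duration=1.0, n_sessions=1,
        reps_per_class_per_session=4, n_classes=2,
        class_band_profiles=[[(2.0, 0.4, 2.0)], [(40.0, 2.0, 2.0)]], seed=5,
    )
    return generate_dataset(cfg)


def cluster_features(n_per_class: int, n_classes: int = 6, dim: int = 48,
                     spread: float = 0.3, seed: int = 0):
    """Strongly separable Gaussian class clusters in feature space."""
    rng = np.random.default_rng(seed)
    centers = 3.0 * rng.normal(0, 1, (n_classes, dim))
    X = np.vstack([centers[c] + spread * rng.standard_normal((n_per_class, dim))
                   for c in range(n_classes)])
    y = np.repeat(np.arange(n_classes), n_per_class)
    perm = rng.permutation(len(X))
    return X[perm], y[perm]
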