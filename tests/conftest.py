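import numpy as np
import pytest

from fannc import ConcentrationMatrix, generate_truth, synthesize_dataset


@pytest.fixture
def toy_cm() -> ConcentrationMatrix:
    """3 compounds × 2 samples, entries 1..6."""
    return ConcentrationMatrix(
        values=np.arange(1.0, 7.0).reshape(3, 2),
        compound_labels=("A", "B", "C"),
        sample_labels=("s1", "s2"),
    )


@pytest.fixture
def truth3():
    """Default-condition ground truth: 15 compounds, 3 sources, 32 samples."""
    return generate_truth(m=15, n=3, r=32, seed=11, separation=0.8)


@pytest.fixture
def noiseless_cm(truth3):
    return synthesize_dataset(truth3, noise_cv=0.0)


@pytest.fixture
def noisy_cm(truth3):
    return synthesize_dataset(truth3, noise_cv=0.05, seed=12)
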