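import numpy as np
import pytest

from mbeeg import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """10 trials x 22 channels x 1125 samples, 4 balanced-ish classes."""
    data = rng.standard_normal((10, 22, 1125)).astype(np.float32)
    labels = np.array([0, 1, 2, 3, 0, 1, 2, 3, 0, 1], dtype=np.int64)
    return EpochSet(
        data=data,
        labels=labels,
        fs=250.0,
        channel_names=[f"ch{i}" for i in range(22)],
        class_names=["left_hand", "right_hand", "feet", "tongue"],
        subject_id="S01",
    )


@pytest.fixture
def tiny_epochs(rng):
    """Small epochs for fast model-level tests (8 channels, 160 samples)."""
    data = rng.standard_normal((12, 8, 160)).astype(np.float32)
    labels = np.array([0, 1, 2, 3] * 3, dtype=np.int64)
    return EpochSet(data=data, labels=labels, fs=80.0,
                    class_names=["a", "b", "c", "d"])
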