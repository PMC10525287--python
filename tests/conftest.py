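import numpy as np
import pytest

from remwave import SyntheticConfig, cut_epochs, filter_and_trim, generate_recording


@pytest.fixture(scope="session")
def separable_dataset():
    """A fixed, strongly class-separable synthetic dataset (>=500 epochs).

    Non-REM epochs carry high-amplitude slow waves, REM epochs low-amplitude
    mixed theta, so delta-band power alone separates the classes.
    """
    cfg = SyntheticConfig(
        n_epochs=520,
        seed=7,
        rem_fraction=0.35,
        leading_wake_epochs=3,
        movement_fraction=0.02,
    )
    rec = generate_recording(cfg)
    epochs = filter_and_trim(cut_epochs(rec.samples, rec.annotations))
    y = np.array([e.binary_label for e in epochs])
    X = np.stack([e.samples for e in epochs])
    return X, y


@pytest.fixture(scope="session")
def small_dataset():
    """A small separable dataset for fast training smoke tests."""
    cfg = SyntheticConfig(n_epochs=90, seed=11, rem_fraction=0.4,
                          leading_wake_epochs=2, movement_fraction=0.0)
    rec = generate_recording(cfg)
    epochs = filter_and_trim(cut_epochs(rec.samples, rec.annotations))
    y = np.array([e.binary_label for e in epochs])
    X = np.stack([e.samples for e in epochs])
    return X, y
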