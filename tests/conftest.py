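import numpy as np
import pytest

from pacnet import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def make_recording(rng):
    """Factory for small random recordings with valid metadata."""

    def _make(n_channels=4, n_samples=1000, fs=1000.0, labels=None, data=None,
              group="wm", state="task"):
        if labels is None:
            labels = [f"C{i + 1}" for i in range(n_channels)]
        if data is None:
            data = rng.standard_normal((len(labels), n_samples))
        return Recording(
            subject_id="s01", group=group, state=state, fs=fs,
            channels=list(labels), data=data,
        )

    return _make
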