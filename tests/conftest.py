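import numpy as np
import pytest

from plvtree.preprocess import EpochSet, EpochWindow

FS = 7.81


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def epochs_from_signal(build, n_trials=4, n_channels=3, fs=FS, window=None):
    """Build an EpochSet from a callable (trial, channel, t) -> samples."""
    win = window or EpochWindow()
    t = win.t_start + np.arange(win.n_samples(fs)) / fs
    data = np.stack(
        [
            np.stack([np.asarray(build(p, c, t), dtype=float) for c in range(n_channels)])
            for p in range(n_trials)
        ]
    )
    labels = [f"CH{c + 1:02d}" for c in range(n_channels)]
    return EpochSet(data=data, fs=fs, channel_labels=labels, window=win)


@pytest.fixture
def cosine_epochs():
    """Pure bin-aligned cosines: phase is known in closed form."""
    freq = 2 * FS / 156  # two cycles per 156-sample epoch, well inside the band

    def build(p, c, t):
        return np.cos(2 * np.pi * freq * t)

    return epochs_from_signal(build), freq
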