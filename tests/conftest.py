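import numpy as np
import pytest

from multirsvp.preprocess import EpochSet


def make_epochs(
    data: np.ndarray,
    fs_hz: float = 600.0,
    labels=None,
    streams=None,
    channel_labels=(),
) -> EpochSet:
    """Wrap a raw (epochs, channels, samples) array as an EpochSet."""
    n = data.shape[0]
    if labels is None:
        labels = np.zeros(n, dtype=bool)
    streams = np.array(
        ["left"] * n if streams is None else streams, dtype=object
    )
    return EpochSet(
        data=np.asarray(data),
        fs_hz=fs_hz,
        labels=np.asarray(labels, dtype=bool),
        image_ids=np.arange(n),
        stream_ids=streams,
        epoch_length_ms=data.shape[2] / fs_hz * 1000.0,
        channel_labels=tuple(channel_labels),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_epochs(rng):
    """400 epochs (40 targets), 4 channels, 600 samples @600 Hz.

    Targets carry a Gaussian bump (peak 300 ms, FWHM 200 ms) through a fixed
    topography; noise is white."""
    n, c, s = 400, 4, 600
    fs = 600.0
    topo = np.array([0.2, 0.4, 1.0, 0.6])
    t = np.arange(s) / fs
    bump = 4.0 * np.exp(-0.5 * ((t - 0.3) / (0.2 / 2.355)) ** 2)
    labels = np.zeros(n, dtype=bool)
    labels[:40] = True
    data = rng.standard_normal((n, c, s)) * 3.0
    data[labels] += topo[:, None] * bump[None, :]
    perm = rng.permutation(n)
    return make_epochs(data[perm], fs, labels[perm]), topo
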