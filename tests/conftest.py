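"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from spikemyo import encode as enc
from spikemyo import preprocess as pp
from spikemyo import synth


@pytest.fixture(scope="session")
def hd_dataset():
    """One subject, one trial, 9 gestures x 8 repetitions, 128 channels.

    The standard small-study condition used for ratio-protocol and sweep
    tests: 2,808 preprocessed windows (9 x 8 x 39).
    """
    cfg = synth.SynthConfig(n_subjects=1, n_trials=1, n_gestures=9,
                            n_repetitions=8, seed=3)
    X, labels = pp.build_dataset(synth.iter_dataset(cfg))
    return X, labels


@pytest.fixture(scope="session")
def hd_spikes(hd_dataset):
    X, labels = hd_dataset
    return enc.encode_batch(X, enc.EncoderConfig()), labels


@pytest.fixture(scope="session")
def tiny_recordings():
    """A handful of raw recordings (2 subjects x 1 trial x 3 gestures x 2)."""
    cfg = synth.SynthConfig(n_subjects=2, n_trials=1, n_gestures=3,
                            n_repetitions=2, seed=7)
    return synth.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_grid_recording():
    """3x3 single-array layout with flat unit signals, for repair tests."""
    layout = synth.ElectrodeLayout(arrays=((3, 3, 10.0),))
    sig = np.ones((9, 500))
    return synth.EmgRecording(signal=sig, sampling_rate=1000.0, subject=0,
                              trial=0, gesture=0, repetition=0, layout=layout)
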