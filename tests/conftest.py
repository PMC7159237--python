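import warnings

import numpy as np
import pytest

from fpvs.paradigm import ScheduleParams
from fpvs.preprocess import Epoch, Recording

# epoch-skipped warnings are expected in edge-case tests
warnings.filterwarnings("ignore", message="trigger at sample")


@pytest.fixture
def params():
    return ScheduleParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sine_recording(freqs_amps, fs=512.0, duration=10.0, n_channels=1,
                        labels=None, events=()):
    """Single- or multi-channel sum of sinusoids, amplitude in μV."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    for f, a in freqs_amps:
        sig += a * np.sin(2 * np.pi * f * t)
    data = np.tile(sig, (n_channels, 1))
    labels = labels or [f"ch{i}" for i in range(n_channels)]
    return Recording(data=data, fs=fs, labels=labels, events=list(events))


def make_sine_epoch(freqs_amps, fs=256.0, duration=59.5, n_channels=1,
                    labels=None, t0=0.0):
    rec = make_sine_recording(freqs_amps, fs=fs, duration=duration,
                              n_channels=n_channels, labels=labels)
    return Epoch(data=rec.data, fs=fs, labels=rec.labels, t0=t0)


def spectrum_amplitude(x, fs, f):
    """Independent single-bin amplitude oracle: 2|X_b|/N at the bin of f."""
    n = len(x)
    b = int(round(f * n / fs))
    return 2.0 * abs(np.fft.rfft(x)[b]) / n
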