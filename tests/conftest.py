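import numpy as np
import pytest

from musupp import synth, spectral
from musupp.types import EEGRecording

#: EEG sampling rate used by most fixtures; divides the 0.5 Hz grid and
#: keeps test signals small
FS = 256.0


@pytest.fixture(scope="session")
def small_study():
    """A compact but complete study exercised by several test modules."""
    cfg = synth.GenerationConfig(
        n_participants=6, n_videos=9,
        video_duration_s=[36, 45, 39, 42, 48, 36, 45, 39, 42],
        eeg_fs_hz=FS, seed=11)
    return synth.generate_study(cfg)


@pytest.fixture(scope="session")
def small_suppression(small_study):
    return spectral.suppression_table(small_study.eeg, small_study.design,
                                      notch_hz=None)


def sinusoid_recording(freq_hz, amp=1.0, duration_s=9.0, fixation_s=3.0,
                       fs=FS, channels=("C3", "C4", "O1", "O2")):
    n = int(round((duration_s + fixation_s) * fs))
    t = np.arange(n) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    return EEGRecording(np.tile(x, (len(channels), 1)), fs, list(channels),
                        onset_index=int(round(fixation_s * fs)),
                        fixation_s=fixation_s)


def brute_force_band_power(segment, fs, f_low, f_high):
    """Independent direct-DFT oracle with the same Hanning taper.

    Evaluates the tapered DFT by explicit summation at every 0.5 Hz
    frequency in [f_low, f_high] and sums the squared moduli.
    """
    n = segment.size
    w = np.hanning(n)
    total = 0.0
    f = f_low
    while f <= f_high + 1e-9:
        k = np.exp(-2j * np.pi * f * np.arange(n) / fs)
        total += abs(np.sum(segment * w * k)) ** 2
        f += 0.5
    return total
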