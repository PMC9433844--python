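"""Core domain containers shared across the pipeline.

The pipeline passes around a small set of plain dataclasses: continuous
affect ratings (:class:`RatingSeries`), multi-channel EEG traces
(:class:`EEGRecording`), frequency bands (:class:`BandSpec`) and the 3 s
epoch segmentation of a recording (:class:`EpochGrid`).  Tabular results
(suppression tables, accuracy tables, model inputs) are ordinary pandas
DataFrames with documented column schemas; see :mod:`musupp.spectral` and
:mod:`musupp.behavior`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: The four scalp sites carried through the whole analysis: central
#: (sensorimotor, mu rhythm) C3/C4 and occipital (visual alpha) O1/O2.
ANALYSIS_CHANNELS = ("C3", "C4", "O1", "O2")

#: Viewing conditions, in the fixed factor order used by the models
#: (Audio-Video is the reference level).
CONDITIONS = ("Audio-Video", "Video-Only", "Audio-Only")

#: Epoch length in seconds used for both EEG power and rating averaging.
EPOCH_LENGTH_S = 3.0


@dataclass
class RatingSeries:
    """One person's continuous 0-100 affect trace for one video.

    Parameters
    ----------
    values
        Slider samples on the 0-100 affect scale, uniformly sampled.
    dt_s
        Sampling step in seconds (0.5 s in the task).
    role
        ``"target"`` (self-report) or ``"observer"`` (inference).
    participant, video
        Optional identifiers; targets have no participant.
    """

    values: np.ndarray
    dt_s: float = 0.5
    role: str = "target"
    participant: Optional[str] = None
    video: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("rating series must be a non-empty 1-D array")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.role not in ("target", "observer"):
            raise ValueError(f"unknown role {self.role!r}")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 100:
            raise ValueError("ratings must lie in [0, 100]")

    @property
    def duration_s(self) -> float:
        return self.values.size * self.dt_s

    def __len__(self) -> int:
        return self.values.size


@dataclass
class EEGRecording:
    """Multi-channel voltage trace with stimulus-onset marker.

    ``samples`` is a (n_channels, n_times) array in microvolts.  The
    recording contains ``fixation_s`` seconds of pre-stimulus fixation;
    ``onset_index`` is the sample at which the stimulus starts.
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    onset_index: int
    fixation_s: float = 5.0
    participant: Optional[str] = None
    video: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = list(self.channel_labels)
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match samples rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (0 <= self.onset_index <= self.samples.shape[1]):
            raise ValueError("onset_index outside the recording")
        if self.onset_index + 1e-9 < round(self.fixation_s * self.fs):
            raise ValueError("onset_index inconsistent with fixation_s")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [f_low, f_high] in Hz.

    ``kind`` records how the band was chosen: the fixed 8-13 Hz mu/alpha
    range, an individualized peak +- 1 Hz band, or the 9-11 Hz default
    used when no spectral peak is identifiable.
    """

    f_low: float
    f_high: float
    kind: str = "fixed"  # fixed | individualized | default_fallback

    def __post_init__(self) -> None:
        if self.f_high <= self.f_low:
            raise ValueError("f_high must exceed f_low")
        if self.kind not in ("fixed", "individualized", "default_fallback"):
            raise ValueError(f"unknown band kind {self.kind!r}")
        width = self.f_high - self.f_low
        if self.kind == "fixed" and not np.isclose(width, 5.0):
            raise ValueError("fixed band must span 5 Hz (8-13)")
        if self.kind in ("individualized", "default_fallback") and not np.isclose(width, 2.0):
            raise ValueError("individualized band must span 2 Hz (peak +- 1)")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)


MU_BAND = BandSpec(8.0, 13.0, kind="fixed")
DEFAULT_FALLBACK_BAND = BandSpec(9.0, 11.0, kind="default_fallback")


@dataclass
class EpochGrid:
    """Non-overlapping, contiguous 3 s windows over a recording.

    ``starts`` holds the first sample of every window; window ``i`` spans
    ``[starts[i], starts[i] + n_samples)``.  Index ``baseline_index``
    designates the baseline window (first 3 s of fixation by default);
    the remaining windows tile the stimulus period, trailing partial
    window dropped.  ``kept`` is flipped to False by artifact rejection.
    """

    starts: np.ndarray
    n_samples: int
    epoch_length_s: float
    baseline_index: int
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        if self.kept is None:
            self.kept = np.ones(self.starts.size, dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.kept.size != self.starts.size:
            raise ValueError("kept flags must match number of epochs")
        if not (0 <= self.baseline_index < self.starts.size):
            raise ValueError("baseline_index out of range")

    @property
    def n_epochs(self) -> int:
        return self.starts.size

    @property
    def stimulus_indices(self) -> np.ndarray:
        """Indices of all non-baseline windows, in temporal order."""
        idx = np.arange(self.n_epochs)
        return idx[idx != self.baseline_index]

    def slices(self):
        return [slice(s, s + self.n_samples) for s in self.starts]
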