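"""EEG band power and mu/alpha suppression indices.

This module turns a raw multi-channel recording into per-epoch band
powers and ln-ratio suppression indices:

1. :func:`preprocess` - 0.5 Hz high-pass, 30 Hz low-pass with a
   24 dB/octave roll-off, mains notch; all zero-phase.
2. :func:`build_epochs` - contiguous 3 s windows; the baseline window is
   the first 3 s of the pre-stimulus fixation (a switch reproduces the
   alternative "first stimulus epoch" baseline).
3. :func:`reject_artifacts` - drop any epoch in which any analysis
   channel exceeds +-100 uV.
4. :func:`epoch_band_power` - Hanning-windowed FFT evaluated on a
   0.5 Hz grid, power summed over band bins (endpoints inclusive).
5. :func:`suppression_index` - S = ln(epoch power / baseline power);
   negative values mean suppression relative to baseline.
6. :func:`individualized_band` - a participant's 2 Hz band centred on
   their own spectral peak in 8-13 Hz, with the 9-11 Hz default when no
   peak stands out of the 1/f background.
7. :func:`suppression_table` - the tidy per-study table feeding the
   statistical models.

A 3 s window has a native resolution of 1/3 Hz; to obtain an exact
0.5 Hz grid each epoch is zero-padded to the smallest multiple of
``2 * fs`` samples that covers it, and power is read off at the bins
that are exact multiples of 0.5 Hz.  This choice is fixed so results
are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .types import (
    ANALYSIS_CHANNELS,
    DEFAULT_FALLBACK_BAND,
    EPOCH_LENGTH_S,
    BandSpec,
    EEGRecording,
    EpochGrid,
)

FREQ_STEP_HZ = 0.5


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def preprocess(
    rec: EEGRecording,
    hp_hz: float = 0.5,
    lp_hz: float = 30.0,
    notch_hz: Optional[float] = 60.0,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Band-pass and notch filter a recording, zero-phase.

    The low-pass is a 4th-order Butterworth (24 dB/octave); the
    high-pass a 2nd-order Butterworth.  Both are applied forward and
    backward (``sosfiltfilt``) so the effective attenuation at the edges
    is at least the nominal roll-off and no phase delay is introduced.
    Set ``notch_hz=None`` to skip the mains notch (e.g. for short
    synthetic traces with no line noise).
    """
    nyq = rec.fs / 2.0
    if rec.fs <= 2.0 * lp_hz:
        raise ValueError(f"fs={rec.fs} Hz cannot support a {lp_hz} Hz low-pass")
    if notch_hz is not None and notch_hz >= nyq:
        raise ValueError(f"notch at {notch_hz} Hz is outside Nyquist ({nyq} Hz)")

    x = rec.samples
    sos_hp = signal.butter(2, hp_hz, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = signal.butter(4, lp_hz, btype="lowpass", fs=rec.fs, output="sos")
    y = signal.sosfiltfilt(sos_hp, x, axis=-1)
    y = signal.sosfiltfilt(sos_lp, y, axis=-1)
    if notch_hz is not None:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
        y = signal.filtfilt(b, a, y, axis=-1)
    return EEGRecording(
        samples=y,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        onset_index=rec.onset_index,
        fixation_s=rec.fixation_s,
        participant=rec.participant,
        video=rec.video,
    )


def rereference(rec: EEGRecording, reference_labels: Sequence[str]) -> EEGRecording:
    """Subtract the mean of the given reference channels (e.g. mastoids).

    Pass-through hook; inert when the reference channels are absent
    (synthetic recordings carry only the four analysis channels).
    """
    missing = [c for c in reference_labels if c not in rec.channel_labels]
    if missing:
        return rec
    ref = np.mean([rec.channel(c) for c in reference_labels], axis=0)
    out = rec.samples - ref[None, :]
    return EEGRecording(out, rec.fs, list(rec.channel_labels), rec.onset_index,
                        rec.fixation_s, rec.participant, rec.video)


# ---------------------------------------------------------------------------
# Epoching and artifact rejection
# ---------------------------------------------------------------------------

def build_epochs(
    rec: EEGRecording,
    epoch_length_s: float = EPOCH_LENGTH_S,
    baseline: str = "fixation",
) -> EpochGrid:
    """Segment a recording into contiguous epochs plus a baseline window.

    With ``baseline="fixation"`` (default) the baseline is the first
    ``epoch_length_s`` of the pre-onset fixation; stimulus epochs tile
    [onset, end), the trailing partial window dropped.  With
    ``baseline="first_stimulus_epoch"`` no fixation window is used and
    the first stimulus epoch doubles as the baseline.
    """
    n_ep = int(round(epoch_length_s * rec.fs))
    if baseline not in ("fixation", "first_stimulus_epoch"):
        raise ValueError(f"unknown baseline mode {baseline!r}")

    stim_starts = np.arange(rec.onset_index, rec.n_times - n_ep + 1, n_ep)
    if baseline == "fixation":
        fix_start = rec.onset_index - int(round(rec.fixation_s * rec.fs))
        if rec.fixation_s + 1e-9 < epoch_length_s or fix_start < 0:
            raise ValueError(
                f"fixation ({rec.fixation_s} s) shorter than epoch length "
                f"({epoch_length_s} s); cannot form a baseline window"
            )
        starts = np.concatenate([[fix_start], stim_starts])
        baseline_index = 0
    else:
        if stim_starts.size == 0:
            raise ValueError("recording too short for a single epoch")
        starts = stim_starts
        baseline_index = 0
    return EpochGrid(starts=starts, n_samples=n_ep,
                     epoch_length_s=epoch_length_s, baseline_index=baseline_index)


def reject_artifacts(
    rec: EEGRecording,
    grid: EpochGrid,
    threshold_uv: float = 100.0,
    channels: Optional[Sequence[str]] = None,
) -> EpochGrid:
    """Mark epochs exceeding +-threshold_uv on any analysis channel.

    The threshold applies jointly across channels: one bad channel drops
    the epoch for all channels.  Returns a new grid; never raises on an
    empty kept set (downstream code must tolerate it).
    """
    if channels is None:
        channels = [c for c in ANALYSIS_CHANNELS if c in rec.channel_labels] \
            or list(rec.channel_labels)
    rows = [rec.channel_labels.index(c) for c in channels]
    kept = grid.kept.copy()
    for i, s in enumerate(grid.starts):
        seg = rec.samples[rows, s:s + grid.n_samples]
        if np.max(np.abs(seg)) > threshold_uv:
            kept[i] = False
    return EpochGrid(starts=grid.starts.copy(), n_samples=grid.n_samples,
                     epoch_length_s=grid.epoch_length_s,
                     baseline_index=grid.baseline_index, kept=kept)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _fft_length(n_samples: int, fs: float) -> int:
    """Smallest multiple of 2*fs samples covering the epoch.

    A grid spacing of exactly ``FREQ_STEP_HZ`` requires the FFT length
    to be a multiple of ``fs / FREQ_STEP_HZ`` = 2*fs samples.
    """
    base = fs / FREQ_STEP_HZ
    if abs(base - round(base)) > 1e-9:
        raise ValueError(f"fs={fs} Hz incompatible with a {FREQ_STEP_HZ} Hz grid")
    base = int(round(base))
    return base * math.ceil(n_samples / base)


def epoch_spectra(rec: EEGRecording, grid: EpochGrid,
                  f_max_hz: float = 30.0) -> Tuple[np.ndarray, np.ndarray]:
    """Hanning-windowed FFT power on the 0.5 Hz grid for every epoch.

    Returns ``(freqs, power)`` with ``power`` shaped
    (n_epochs, n_channels, n_freqs).  Power is computed for all epochs
    regardless of their kept flag (callers filter); it is the squared
    modulus of the tapered, zero-padded DFT, unnormalized - every use
    downstream is a ratio or an argmax, so the constant cancels.
    """
    n = grid.n_samples
    nfft = _fft_length(n, rec.fs)
    window = np.hanning(n)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)
    sel = freqs <= f_max_hz + 1e-9
    # keep only exact multiples of the 0.5 Hz step
    step = int(round(FREQ_STEP_HZ * nfft / rec.fs))
    grid_idx = np.arange(0, np.sum(sel), step)
    segs = np.stack([rec.samples[:, s:s + n] for s in grid.starts])  # (E, C, n)
    tapered = segs * window[None, None, :]
    spec = np.fft.rfft(tapered, n=nfft, axis=-1)
    power = np.abs(spec[:, :, : int(np.sum(sel))]) ** 2
    return freqs[sel][grid_idx], power[:, :, grid_idx]


def band_power_from_spectrum(freqs: np.ndarray, power: np.ndarray,
                             band: BandSpec) -> np.ndarray:
    """Integrated power: inclusive sum over bins f_low <= f <= f_high."""
    mask = (freqs >= band.f_low - 1e-9) & (freqs <= band.f_high + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} contains no grid frequencies")
    return power[..., mask].sum(axis=-1)


def epoch_band_power(rec: EEGRecording, grid: EpochGrid, band: BandSpec,
                     lp_hz: float = 30.0, hp_hz: float = 0.5) -> np.ndarray:
    """Per-epoch, per-channel integrated band power, shape (E, C)."""
    if band.f_low < hp_hz or band.f_high > lp_hz:
        raise ValueError(f"band {band.f_low}-{band.f_high} Hz outside the "
                         f"filtered range [{hp_hz}, {lp_hz}] Hz")
    freqs, power = epoch_spectra(rec, grid, f_max_hz=lp_hz)
    return band_power_from_spectrum(freqs, power, band)


def suppression_index(epoch_power: np.ndarray, baseline_power: float) -> np.ndarray:
    """S = ln(epoch_power / baseline_power); NaN where undefined.

    Negative S means less power than baseline, i.e. suppression.  A
    zero or negative baseline (or epoch) power yields NaN rather than
    +-inf, so degenerate trials are flagged missing instead of
    propagating infinities.
    """
    epoch_power = np.asarray(epoch_power, dtype=float)
    out = np.full(epoch_power.shape, np.nan)
    if baseline_power > 0:
        ok = epoch_power > 0
        out[ok] = np.log(epoch_power[ok] / baseline_power)
    return out


# ---------------------------------------------------------------------------
# Individualized mu band
# ---------------------------------------------------------------------------

@dataclass
class PeakSearchConfig:
    """Controls automatic peak identification in the 8-13 Hz range."""

    search_low_hz: float = 8.0
    search_high_hz: float = 13.0
    #: fraction by which the candidate bin must exceed the fitted 1/f trend
    prominence_frac: float = 0.10
    #: frequency range used to fit the 1/f background (mu/alpha excluded);
    #: restricted to 3-16 Hz where the band-pass filters alter power by
    #: <2%, so roll-off cannot tilt the fitted line and bias prominence
    trend_fit_low_hz: float = 3.0
    trend_fit_high_hz: float = 16.0
    trend_exclude: Tuple[float, float] = (7.0, 14.0)
    clip_to_search: bool = False


def average_spectrum(recordings: Iterable[Tuple[EEGRecording, EpochGrid]],
                     channels: Optional[Sequence[str]] = None,
                     f_max_hz: float = 30.0) -> Tuple[np.ndarray, np.ndarray]:
    """Participant-level mean spectrum: epochs within video, then videos.

    Kept stimulus epochs are averaged within each recording, those
    per-video means are averaged across recordings, and finally across
    the requested channels (all analysis channels by default).
    """
    per_video = []
    freqs_ref = None
    for rec, grid in recordings:
        freqs, power = epoch_spectra(rec, grid, f_max_hz=f_max_hz)
        keep = grid.kept.copy()
        keep[grid.baseline_index] = False
        if not keep.any():
            continue
        if channels is None:
            rows = [rec.channel_labels.index(c) for c in ANALYSIS_CHANNELS
                    if c in rec.channel_labels]
        else:
            rows = [rec.channel_labels.index(c) for c in channels]
        mean_video = power[keep][:, rows, :].mean(axis=(0, 1))
        per_video.append(mean_video)
        freqs_ref = freqs
    if not per_video:
        raise ValueError("no kept epochs in any recording")
    return freqs_ref, np.mean(per_video, axis=0)


def find_peak(freqs: np.ndarray, spectrum: np.ndarray,
              cfg: PeakSearchConfig = PeakSearchConfig()) -> Optional[float]:
    """Frequency of the maximum local peak above the 1/f trend, or None.

    The 1/f background is a straight line fitted to log-power versus
    log-frequency outside the mu/alpha range; the best in-range bin must
    be a local maximum and exceed the trend prediction by the prominence
    fraction.  Ties break toward the lower frequency (first argmax).
    """
    fit = (freqs >= cfg.trend_fit_low_hz) & (freqs <= cfg.trend_fit_high_hz) \
        & ~((freqs >= cfg.trend_exclude[0]) & (freqs <= cfg.trend_exclude[1])) \
        & (spectrum > 0)
    trend = np.zeros_like(freqs)
    pos = freqs > 0
    if fit.sum() >= 2:
        coef = np.polyfit(np.log(freqs[fit]), np.log(spectrum[fit]), 1)
        trend[pos] = np.exp(np.polyval(coef, np.log(freqs[pos])))
    # else: degenerate spectrum, no background to beat

    search = (freqs >= cfg.search_low_hz - 1e-9) & (freqs <= cfg.search_high_hz + 1e-9)
    idx = np.flatnonzero(search)
    order = idx[np.argsort(-spectrum[idx], kind="stable")]
    for i in order:
        left = spectrum[i - 1] if i > 0 else -np.inf
        right = spectrum[i + 1] if i + 1 < spectrum.size else -np.inf
        if spectrum[i] < max(left, right):
            continue  # not a local maximum
        if spectrum[i] >= (1.0 + cfg.prominence_frac) * trend[i]:
            return float(freqs[i])
        break  # the global in-range max failed prominence -> fallback
    return None


def individualized_band(recordings: Iterable[Tuple[EEGRecording, EpochGrid]],
                        cfg: PeakSearchConfig = PeakSearchConfig(),
                        channels: Optional[Sequence[str]] = None) -> BandSpec:
    """A participant's peak +- 1 Hz band, or the 9-11 Hz default.

    Averages kept-epoch spectra within each video, then across videos,
    and centres a 2 Hz band on the identified peak.  When no local peak
    clears the prominence criterion the 9-11 Hz default band (centre
    10 Hz) is returned with ``kind="default_fallback"``.  The band is
    not clipped to the search range unless ``cfg.clip_to_search``.
    """
    freqs, spec = average_spectrum(recordings, channels=channels)
    peak = find_peak(freqs, spec, cfg)
    if peak is None:
        return DEFAULT_FALLBACK_BAND
    lo = peak - 1.0
    if cfg.clip_to_search:
        # shift (not shrink) the 2 Hz band back inside the search range
        lo = min(max(lo, cfg.search_low_hz), cfg.search_high_hz - 2.0)
    return BandSpec(lo, lo + 2.0, kind="individualized")


# ---------------------------------------------------------------------------
# Study-level suppression table
# ---------------------------------------------------------------------------

def suppression_table(
    recordings: Mapping[Tuple[str, str], EEGRecording],
    design: pd.DataFrame,
    band_mode: str = "fixed",
    baseline: str = "fixation",
    threshold_uv: float = 100.0,
    do_preprocess: bool = True,
    notch_hz: Optional[float] = 60.0,
    peak_cfg: PeakSearchConfig = PeakSearchConfig(),
    drop_log: Optional[list] = None,
) -> pd.DataFrame:
    """Per-epoch suppression indices for a whole study.

    Parameters
    ----------
    recordings
        Mapping (participant, video) -> raw EEGRecording.
    design
        Table with columns ``participant, video, condition``.
    band_mode
        ``"fixed"`` (8-13 Hz everywhere) or ``"individualized"``
        (per-participant 2 Hz band shared across channels).
    drop_log
        Optional list collecting dicts describing dropped epochs/trials.

    Returns a tidy DataFrame with columns ``participant, video,
    condition, channel, epoch, band_kind, f_low, f_high, S`` - one row
    per kept stimulus epoch per channel.  Trial means are obtained with
    :func:`trial_means`.
    """
    if band_mode not in ("fixed", "individualized"):
        raise ValueError(f"unknown band_mode {band_mode!r}")

    prepared: Dict[Tuple[str, str], Tuple[EEGRecording, EpochGrid]] = {}
    for key, rec in recordings.items():
        pre = preprocess(rec, notch_hz=notch_hz) if do_preprocess else rec
        grid = build_epochs(pre, baseline=baseline)
        grid = reject_artifacts(pre, grid, threshold_uv=threshold_uv)
        prepared[key] = (pre, grid)
        if drop_log is not None:
            for i in np.flatnonzero(~grid.kept):
                drop_log.append({"participant": key[0], "video": key[1],
                                 "epoch": int(i), "reason": "amplitude>threshold"})

    bands: Dict[str, BandSpec] = {}
    if band_mode == "individualized":
        participants = sorted({p for p, _ in prepared})
        for p in participants:
            recs = [prepared[k] for k in prepared if k[0] == p]
            try:
                bands[p] = individualized_band(recs, cfg=peak_cfg)
            except ValueError:
                bands[p] = DEFAULT_FALLBACK_BAND

    cond = {(r.participant, r.video): r.condition for r in design.itertuples()}
    rows = []
    from .types import MU_BAND
    for (p, v), (rec, grid) in sorted(prepared.items()):
        band = bands.get(p, MU_BAND) if band_mode == "individualized" else MU_BAND
        chans = [c for c in ANALYSIS_CHANNELS if c in rec.channel_labels]
        ch_rows = [rec.channel_labels.index(c) for c in chans]
        power = epoch_band_power(rec, grid, band)  # (E, C_all)
        if not grid.kept[grid.baseline_index]:
            if drop_log is not None:
                drop_log.append({"participant": p, "video": v, "epoch": "baseline",
                                 "reason": "baseline epoch rejected"})
            continue
        for ci, c in zip(ch_rows, chans):
            base = power[grid.baseline_index, ci]
            s_vals = suppression_index(power[:, ci], base)
            for rank, ei in enumerate(grid.stimulus_indices):
                if not grid.kept[ei]:
                    continue
                rows.append({"participant": p, "video": v,
                             "condition": cond.get((p, v)), "channel": c,
                             "epoch": rank, "band_kind": band.kind,
                             "f_low": band.f_low, "f_high": band.f_high,
                             "S": s_vals[ei]})
    return pd.DataFrame(rows, columns=["participant", "video", "condition",
                                       "channel", "epoch", "band_kind",
                                       "f_low", "f_high", "S"])


def trial_means(supp: pd.DataFrame) -> pd.DataFrame:
    """Mean S over kept stimulus epochs, wide by channel.

    Returns one row per participant x video with columns ``S_C3, S_C4,
    S_O1, S_O2``; a trial with no kept epochs for a channel gets NaN.
    """
    wide = (supp.pivot_table(index=["participant", "video", "condition"],
                             columns="channel", values="S", aggfunc="mean")
            .rename(columns=lambda c: f"S_{c}")
            .reset_index())
    wide.columns.name = None
    return wide
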