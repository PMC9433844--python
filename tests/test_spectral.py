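"""Spectral pipeline: filtering, epoching, band power, suppression, bands."""

import numpy as np
import pytest

from musupp import spectral, synth
from musupp.types import (
    DEFAULT_FALLBACK_BAND,
    MU_BAND,
    BandSpec,
    EEGRecording,
    EpochGrid,
)
from conftest import FS, brute_force_band_power, sinusoid_recording


def _band_power_of(x, fs, band=MU_BAND, fixation_s=3.0):
    rec = EEGRecording(np.atleast_2d(x), fs, ["C4"],
                       onset_index=int(fixation_s * fs), fixation_s=fixation_s)
    grid = spectral.build_epochs(rec)
    return rec, grid, spectral.epoch_band_power(rec, grid, band)


class TestPreprocess:
    def test_stopband_attenuation_at_45hz(self):
        rec = sinusoid_recording(45.0, amp=10.0, duration_s=30.0)
        out = spectral.preprocess(rec, notch_hz=None)
        # compare band power at 45 Hz before/after on interior epochs
        seg_in = rec.channel("C4")[int(6 * FS):int(9 * FS)]
        seg_out = out.channel("C4")[int(6 * FS):int(9 * FS)]
        p_in = brute_force_band_power(seg_in, FS, 45.0, 45.0)
        p_out = brute_force_band_power(seg_out, FS, 45.0, 45.0)
        assert 10 * np.log10(p_in / p_out) >= 24.0

    def test_passband_10hz_amplitude_preserved(self):
        rec = sinusoid_recording(10.0, amp=10.0, duration_s=30.0)
        out = spectral.preprocess(rec, notch_hz=None)
        interior = slice(int(6 * FS), int(24 * FS))
        ratio = (np.abs(out.channel("C4")[interior]).max()
                 / np.abs(rec.channel("C4")[interior]).max())
        assert abs(ratio - 1.0) < 0.05

    def test_zero_input_zero_output(self):
        rec = EEGRecording(np.zeros((4, int(12 * FS))), FS,
                           ["C3", "C4", "O1", "O2"],
                           onset_index=int(3 * FS), fixation_s=3.0)
        out = spectral.preprocess(rec)
        assert np.allclose(out.samples, 0.0)

    def test_notch_outside_nyquist_rejected(self):
        rec = sinusoid_recording(10.0, fs=100.0)
        with pytest.raises(ValueError, match="[Nn]yquist"):
            spectral.preprocess(rec, notch_hz=60.0)

    def test_fs_too_low_for_lowpass_rejected(self):
        rec = sinusoid_recording(10.0, fs=50.0)
        with pytest.raises(ValueError):
            spectral.preprocess(rec, lp_hz=30.0)


class TestEpoching:
    @pytest.mark.parametrize("duration_s,n_epochs", [(120, 40), (105, 35), (100, 33)])
    def test_stimulus_epoch_counts(self, duration_s, n_epochs):
        rec = sinusoid_recording(10.0, duration_s=duration_s, fixation_s=5.0)
        grid = spectral.build_epochs(rec)
        assert grid.stimulus_indices.size == n_epochs

    def test_baseline_is_first_3s_of_fixation(self):
        rec = sinusoid_recording(10.0, duration_s=12.0, fixation_s=5.0)
        grid = spectral.build_epochs(rec)
        assert grid.starts[grid.baseline_index] == rec.onset_index - int(5 * FS)

    def test_first_stimulus_epoch_baseline_mode(self):
        rec = sinusoid_recording(10.0, duration_s=12.0, fixation_s=5.0)
        grid = spectral.build_epochs(rec, baseline="first_stimulus_epoch")
        assert grid.starts[grid.baseline_index] == rec.onset_index

    def test_short_fixation_rejected(self):
        rec = sinusoid_recording(10.0, duration_s=12.0, fixation_s=2.0)
        with pytest.raises(ValueError, match="fixation"):
            spectral.build_epochs(rec)


class TestArtifactRejection:
    def test_below_threshold_keeps_all(self):
        rec = sinusoid_recording(10.0, amp=99.9, duration_s=12.0)
        grid = spectral.build_epochs(rec)
        out = spectral.reject_artifacts(rec, grid)
        assert out.kept.all()

    def test_single_excursion_drops_exactly_that_epoch(self):
        rec = sinusoid_recording(10.0, amp=10.0, duration_s=21.0)
        grid = spectral.build_epochs(rec)
        # stimulus epoch rank 4 -> grid index 5 (baseline is index 0)
        target = grid.starts[5] + 17
        rec.samples[1, target] = 150.0
        out = spectral.reject_artifacts(rec, grid)
        expected = np.ones(grid.n_epochs, bool)
        expected[5] = False
        assert np.array_equal(out.kept, expected)

    def test_planted_excursions_match_bruteforce_scan(self):
        rng = np.random.default_rng(42)
        n = int(33 * FS)
        x = rng.normal(0, 20, size=(4, n))
        x = np.clip(x, -95, 95)
        rec = EEGRecording(x, FS, ["C3", "C4", "O1", "O2"],
                           onset_index=int(3 * FS), fixation_s=3.0)
        grid = spectral.build_epochs(rec)
        bad = rng.choice(grid.n_epochs, size=4, replace=False)
        for b in bad:
            ch = rng.integers(4)
            rec.samples[ch, grid.starts[b] + rng.integers(grid.n_samples)] = 130.0
        out = spectral.reject_artifacts(rec, grid)
        # independent scan oracle
        oracle = np.array([np.max(np.abs(
            rec.samples[:, s:s + grid.n_samples])) <= 100.0
            for s in grid.starts])
        assert np.array_equal(out.kept, oracle)
        assert set(np.flatnonzero(~out.kept)) == set(bad)


class TestBandPower:
    def test_matches_direct_dft_oracle_on_random_signals(self):
        rng = np.random.default_rng(7)
        n = int(3 * FS)
        worst = 0.0
        for _ in range(50):
            x = rng.normal(0, 10, n)
            rec = EEGRecording(x[None, :], FS, ["C4"], onset_index=0,
                               fixation_s=0.0)
            grid = EpochGrid(starts=[0], n_samples=n, epoch_length_s=3.0,
                             baseline_index=0)
            got = spectral.epoch_band_power(rec, grid, MU_BAND)[0, 0]
            want = brute_force_band_power(x, FS, 8.0, 13.0)
            worst = max(worst, abs(got - want) / want)
        assert worst <= 1e-8

    def test_dc_signal_has_no_mu_band_power(self):
        _, _, bp = _band_power_of(np.full(int(12 * FS), 5.0), FS)
        dc_power = (5.0 * np.hanning(int(3 * FS)).sum()) ** 2
        assert np.all(bp / dc_power < 1e-8)

    def test_quadratic_amplitude_scaling(self):
        t = np.arange(int(12 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        _, _, bp1 = _band_power_of(x, FS)
        _, _, bp2 = _band_power_of(2 * x, FS)
        assert np.allclose(bp2, 4 * bp1, rtol=1e-12)

    def test_band_outside_filtered_range_rejected(self):
        rec = sinusoid_recording(10.0, duration_s=9.0)
        grid = spectral.build_epochs(rec)
        with pytest.raises(ValueError, match="outside"):
            spectral.epoch_band_power(rec, grid, BandSpec(33.0, 38.0, "fixed"))

    def test_epoch_shift_permutes_powers(self):
        """Shifting by whole epochs permutes, never alters, epoch powers."""
        rng = np.random.default_rng(3)
        n_ep = int(3 * FS)
        x = rng.normal(0, 10, 6 * n_ep)
        shifted = np.roll(x, 2 * n_ep)
        for sig, idx in ((x, [0, 1, 2, 3]), (shifted, [2, 3, 4, 5])):
            rec = EEGRecording(sig[None, :], FS, ["C4"], onset_index=0,
                               fixation_s=0.0)
            grid = EpochGrid(starts=np.arange(6) * n_ep, n_samples=n_ep,
                             epoch_length_s=3.0, baseline_index=0)
            bp = spectral.epoch_band_power(rec, grid, MU_BAND)[:, 0]
            if sig is x:
                ref = bp
        assert np.allclose(ref[:4], bp[2:6], rtol=1e-12)


class TestSuppressionIndex:
    @pytest.mark.parametrize("ratio,expected", [(1.0, 0.0), (0.5, np.log(0.5)),
                                                (np.e, 1.0)])
    def test_log_ratio_values(self, ratio, expected):
        assert spectral.suppression_index(np.array([ratio]), 1.0)[0] == \
            pytest.approx(expected, abs=1e-12)

    def test_degenerate_powers_flagged_missing(self):
        assert np.isnan(spectral.suppression_index(np.array([1.0]), 0.0)[0])
        assert np.isnan(spectral.suppression_index(np.array([0.0]), 1.0)[0])

    def test_attenuated_oscillation_matches_closed_form(self):
        """Noise-free: attenuating amplitude by a gives S = ln(a^2)."""
        for a in (0.8, 0.5):
            rec = synth.generate_eeg(15.0, FS, 10.0, np.ones(5),
                                     fixation_s=5.0, noise_sd=0.0,
                                     attenuation_max=1 - a, seed=0)
            grid = spectral.build_epochs(rec)
            bp = spectral.epoch_band_power(rec, grid, MU_BAND)
            c4 = rec.channel_labels.index("C4")
            S = spectral.suppression_index(bp[:, c4], bp[grid.baseline_index, c4])
            assert S[grid.stimulus_indices].mean() == \
                pytest.approx(np.log(a * a), abs=1e-9)

    def test_amplitude_change_moves_s_in_signed_direction(self):
        """Less amplitude than baseline -> lower S; more -> higher S."""
        t = np.arange(int(9 * FS)) / FS
        base = np.sin(2 * np.pi * 10 * t[: int(3 * FS)])
        for a, sign in ((0.5, -1), (1.5, +1)):
            x = np.concatenate([base, a * base, a * a * base])
            rec = EEGRecording(x[None, :], FS, ["C4"],
                               onset_index=int(3 * FS), fixation_s=3.0)
            grid = spectral.build_epochs(rec)
            bp = spectral.epoch_band_power(rec, grid, MU_BAND)[:, 0]
            S = spectral.suppression_index(bp, bp[grid.baseline_index])
            stim = S[grid.stimulus_indices]
            assert np.all(np.sign(stim) == sign)
            assert stim[1] * sign > stim[0] * sign  # strictly monotone


class TestIndividualizedBand:
    def _recs_with_peak(self, peak, seed, n_videos=3, duration=60.0):
        recs = []
        for v in range(n_videos):
            rec = synth.generate_eeg(duration, FS, peak, np.zeros(int(duration // 3)),
                                     fixation_s=5.0, seed=seed * 100 + v)
            pre = spectral.preprocess(rec, notch_hz=None)
            recs.append((pre, spectral.build_epochs(pre)))
        return recs

    @pytest.mark.parametrize("peak", [8.5, 10.5, 11.5])
    def test_planted_peak_recovered_within_half_hz(self, peak):
        band = spectral.individualized_band(self._recs_with_peak(peak, 5))
        assert band.kind == "individualized"
        assert abs(band.center - peak) <= 0.5 + 1e-9
        assert band.f_high - band.f_low == pytest.approx(2.0)

    def test_boundary_peak_at_8hz_gives_7_to_9(self):
        band = spectral.individualized_band(self._recs_with_peak(8.0, 6))
        assert (band.f_low, band.f_high) == (7.0, 9.0)

    def test_pure_noise_returns_default_fallback(self):
        recs = []
        for v in range(9):
            rng = np.random.default_rng(700 + v)
            noise = np.vstack([synth.pink_noise(int(95 * FS), rng, sd=10.0)
                               for _ in range(4)])
            rec = EEGRecording(noise, FS, ["C3", "C4", "O1", "O2"],
                               onset_index=int(5 * FS), fixation_s=5.0)
            pre = spectral.preprocess(rec, notch_hz=None)
            recs.append((pre, spectral.build_epochs(pre)))
        band = spectral.individualized_band(recs)
        assert band == DEFAULT_FALLBACK_BAND

    def test_fallback_iff_prominence_fails_on_same_spectrum(self):
        """The decision is a pure function of the averaged spectrum."""
        recs = self._recs_with_peak(10.5, 8)
        freqs, spec = spectral.average_spectrum(recs)
        peak = spectral.find_peak(freqs, spec)
        band = spectral.individualized_band(recs)
        assert (peak is None) == (band.kind == "default_fallback")

    def test_no_kept_epochs_rejected(self):
        rec = sinusoid_recording(10.0, amp=500.0, duration_s=9.0)
        grid = spectral.build_epochs(rec)
        grid = spectral.reject_artifacts(rec, grid)
        with pytest.raises(ValueError, match="kept"):
            spectral.individualized_band([(rec, grid)])


class TestSuppressionTable:
    def test_row_count_is_kept_epochs_times_channels(self, small_study,
                                                     small_suppression):
        supp = small_suppression
        counts = supp.groupby(["participant", "video"]).size()
        assert (counts % 4 == 0).all()
        n_trials = len(small_study.design)
        assert supp.groupby(["participant", "video"]).ngroups == n_trials

    def test_zero_engagement_grand_mean_near_zero(self):
        cfg_durations = [36, 36, 36]
        recs, design_rows = {}, []
        for v, dur in enumerate(cfg_durations):
            rec = synth.generate_eeg(dur, FS, 10.0, np.zeros(dur // 3),
                                     fixation_s=5.0, seed=50 + v,
                                     participant="P01", video=f"V{v+1}")
            recs[("P01", f"V{v+1}")] = rec
            design_rows.append({"participant": "P01", "video": f"V{v+1}",
                                "condition": "Audio-Video"})
        import pandas as pd
        supp = spectral.suppression_table(recs, pd.DataFrame(design_rows),
                                          notch_hz=None)
        assert abs(supp["S"].mean()) < 0.15

    def test_individualized_mode_changes_band_metadata_only(self, small_study):
        supp = spectral.suppression_table(small_study.eeg, small_study.design,
                                          band_mode="individualized",
                                          notch_hz=None)
        assert set(supp["band_kind"]) <= {"individualized", "default_fallback"}
        assert list(supp.columns) == ["participant", "video", "condition",
                                      "channel", "epoch", "band_kind",
                                      "f_low", "f_high", "S"]

    def test_engaged_c4_is_suppressed_relative_to_occipital_rest(self, small_study,
                                                                 small_suppression):
        """C4 suppression tracks the planted engagement ordering."""
        merged = small_suppression.merge(small_study.truth["trials"],
                                         on=["participant", "video", "condition"])
        c4 = merged[merged.channel == "C4"]
        hi = c4[c4.engagement_mean > 0.6]["S"].mean()
        lo = c4[c4.engagement_mean < 0.4]["S"].mean()
        assert hi < lo < 0.1
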