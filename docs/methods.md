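# Methods

`musupp` implements an analysis pipeline linking EEG mu-rhythm
suppression over sensorimotor sites to behavioral empathic accuracy in
naturalistic continuous-rating studies, together with a synthetic-study
generator that makes every stage testable without real recordings.

## Spectral pipeline

**Filtering.** Recordings are band-passed with a 2nd-order Butterworth
high-pass at 0.5 Hz and a 4th-order Butterworth low-pass at 30 Hz
(24 dB/octave), plus an optional mains notch (60 Hz default; 50 Hz
selectable — the appropriate value depends on the recording site's
mains frequency and is a config parameter).  All filters are applied
forward and backward (zero phase), so the effective stop-band
attenuation is at least the nominal roll-off.

**Epoching and baseline.** Each video is tiled with contiguous 3 s
epochs from stimulus onset; a trailing partial window is dropped.  The
baseline window defaults to the first 3 s of the pre-stimulus fixation
— the standard event-related-desynchronization reference — with a
`baseline="first_stimulus_epoch"` switch that instead uses the first
stimulus epoch, since both conventions appear in the literature on this
paradigm.

**Artifact rejection.** Epochs in which any analysis channel exceeds
±100 µV are dropped jointly for all four channels (a per-channel rule
would desynchronize the channels' epoch sets and complicate the
trial-level merge; the joint rule mirrors common practice).  A rejected
baseline invalidates the whole trial; the drop ledger records every
exclusion with a reason.

**Band power.** Per epoch and channel, power is the squared modulus of
the Hanning-tapered FFT evaluated on an exact 0.5 Hz grid, summed over
all bins with f_low ≤ f ≤ f_high (both endpoints inclusive; the grid
makes ties impossible).  A 3 s window natively resolves 1/3 Hz, so each
epoch is zero-padded to the smallest multiple of `2·fs` samples that
covers it and power is read off at the bins that are exact multiples of
0.5 Hz.  This choice is fixed so results are bit-reproducible, and the
whole path is verified against an independent direct-DFT oracle to
1e−8 relative error.  Power is left unnormalized: every downstream use
is a ratio (suppression index) or an argmax (peak detection), so any
constant cancels.

**Suppression index.** S = ln(epoch power / baseline power).  Negative
values mean suppression.  The log handles the lower-bounded, skewed
ratio distribution; zero or negative powers yield NaN (flagged missing)
rather than ±∞.

**Individualized mu bands.** For each participant, kept-epoch spectra
are averaged within each video, then across videos and across the four
analysis channels, and the band is the 2 Hz window centred on the
spectral peak in 8–13 Hz.  Peak identification is automated: the
candidate is the largest in-range local maximum, and it must exceed a
1/f background fit by a prominence fraction (default 10%).  The
background is a straight line in log power versus log frequency fitted
over 2–20 Hz excluding 7–14 Hz; the fit range deliberately stays inside
the filter passband, because the 30 Hz low-pass already attenuates
power noticeably by 25 Hz and would otherwise tilt the line and
under-predict the 8–13 Hz background (producing spurious detections on
featureless spectra).  When no candidate clears the criterion the
detector returns the 9–11 Hz default band deterministically.  Ties
break toward the lower frequency.  A boundary peak (e.g. 8.0 Hz) gives
a band extending outside 8–13 Hz (7–9 Hz); a config flag clips instead.
The band is shared across channels; in the generator the central mu and
occipital alpha oscillations share one individual rhythm frequency per
participant, so cross-channel averaging cannot mis-centre the band.

## Behavioral scores

Ratings (0–100, every 0.5 s) are averaged over the same 3 s epochs as
the EEG (trailing partial window dropped).  **Empathic accuracy** is
the Pearson correlation of observer and target epoch means for one
video; it is missing (not zero) when either side is constant, and is
used raw — no Fisher z — because the models take the correlation score
directly (a Fisher-z option exists but is off by default).  **Change
detection** classifies each epoch-to-epoch transition as
increase/decrease/maintain and scores a binary success when observer
and target labels match.  The maintain threshold ε defaults to 0:
untouched-slider epochs produce exact equality, and ε = 0 keeps the
labels invariant under any strictly increasing rescaling of the rating
scale.  For noisy real sliders ε is configurable.  Labels start at the
second epoch (a "change from the previous epoch" is undefined for the
first), so a video with n epochs contributes n − 1 change rows.

## Statistical models

Both levels use crossed random intercepts for participant and video,
because every participant sees every video.

**Video level.** EA ~ S_C3 + S_C4 + S_O1 + S_O2 + condition, linear
mixed model fit by REML (ML for the ladder).  The implementation
profiles β and σ² out of the likelihood, leaving a 2-parameter search
over the variance ratios; the Woodbury identity keeps every evaluation
at the scale of the number of random levels, so a fit takes
milliseconds and the calibration studies below are cheap.  Estimates
agree with `lme4::lmer` to ~1e−5 (cross-checked in the test suite).
Wald t statistics use n − p degrees of freedom.

**Epoch level.** Change-detection success ~ epoch-wise suppression +
condition, binomial GLMM with logit link, fit by the Laplace
approximation (joint Newton mode of (β, u), outer search over the two
intercept variances) — the same approximation `lme4::glmer` uses at
nAGQ = 1, and the two agree to ~1e−3 in the cross-check.  The EEG epoch
t is paired with the behavioral change from epoch t − 1 to t
(contemporaneous pairing; recorded in the fit metadata).  A
single-class outcome raises a separation error rather than fitting.

**Hierarchical ladder.** Four nested models — random effects only,
+suppression, +condition, +interaction (all channels × condition, or
C4 × condition only for the replication variant) — each fit by maximum
likelihood and compared by likelihood-ratio tests.  Small-sample
Kenward–Roger F corrections are not available in this stack; the
LRT fallback is used at both levels and recorded in the comparison
metadata.  Under pure-noise generation the step p-values are uniform
to within Kolmogorov–Smirnov tolerance over 500 simulations (measured
by the reproduction script).

**Contrasts.** The three pairwise condition contrasts (AV−VO, AV−AO,
AO−VO) are formed at the sample means of the suppression predictors
(treatment coding, Audio-Video reference) and Bonferroni-adjusted with
m = 3, capped at 1.  Without interaction terms the AV−VO contrast
equals the negated Video-Only coefficient exactly (asserted in tests).

**Outlier rule.** Optional single-pass removal of trials whose EA lies
more than k SD (default 2) from the grand mean; mean and SD are never
recomputed after removal.  Off by default (the small-sample analysis
convention); enabled via `k_sd` for the replication convention.

**Missingness.** Trials with no kept epochs, or with undefined EA, drop
listwise from the video-level table; predictors are entered raw (a
centering switch exists but is off, since nothing indicates
standardization in the source analyses).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the physics of EEG:

- **Targets** are bounded random walks on the 0–100 slider with
  exponentially spaced change points; segments hold (exact equality →
  maintain epochs), ramp, or jump.  Durations default to 105–228 s.
- **Observers** are fidelity-weighted mixtures of the (0.5 s lagged)
  target and an independent pseudo-target, plus slider noise, clipped
  to the scale.  Fidelity is the true accuracy knob.
- **EEG** is 1/f-shaped Gaussian noise (10 µV SD) plus a sinusoid at
  the participant's individual rhythm frequency (drawn U(8.5, 12.5)):
  mu on the central channels, alpha on the occipital ones.  The
  oscillation amplitude (4 µV, giving an in-band power SNR of ≈3:1 on a
  3 s epoch — calibrated once and frozen) is scaled by
  1 − a_max·latent per epoch, with a_max = 0.5.  C4 carries the full
  per-trial "engagement" latent, C3 a third of it (the coupling under
  test is right-lateralized), and O1/O2 follow a separate "visual
  attention" latent, so channel-specific effects are distinguishable
  from shared variance.  Five seconds of fixation (latent 0) precede
  onset.
- **Coupling.** Condition sets the engagement, visual and fidelity
  baselines (engagement highest for Audio-Video; visual attention
  highest for silent video; fidelity highest when the narrative is
  audible).  Within condition, each trial's fidelity deviates from its
  condition baseline in proportion to the trial's predicted C4
  suppression (closed form: S = ln((a²·SNR + 1)/(SNR + 1))), with
  slope `coupling_beta`.  The default, −0.9 on the fidelity-per-unit-S
  scale, was calibrated once so that the fitted video-level C4
  coefficient on generated studies lands near −0.2 — the magnitude
  scale of the reference analyses — after attenuation through the
  EA(fidelity) mapping and the measurement noise in trial-mean S; it is
  frozen and stored in the truth block.
- **Truth.** Every latent needed by a recovery test (per-participant
  peak frequency, per-trial engagement and fidelity, the coupling) is
  retained in `StudyDataset.truth` and written to `truth.json` on disk.

What the generator does *not* emulate: ocular or muscle artifacts
separable by ICA, volume conduction, non-sinusoidal mu waveshape,
rater-specific slider habits, or semantic stimulus content.  Passing
tests therefore demonstrate that the pipeline recovers what it is
supposed to recover under its own statistical assumptions — not that
those assumptions hold for any particular real dataset.

## Model-level simulators

Coverage and type-I-error claims are only well-defined when the
generative model equals the fitted model, so `simulate_trial_table`
and `simulate_epoch_table` draw directly from the mixed models with
planted coefficients (defaults on the scale of the reference analyses:
e.g. a −0.21 video-level and −0.12 epoch-level C4 slope, residual
variance 0.08, video intercept variance 0.04).  The full EEG chain is
exercised qualitatively — sign and ordering checks — in separate
end-to-end tests; its realized slope is necessarily an attenuated,
nonlinear image of the planted coupling, so it is not used for
coverage arithmetic.

## Validation studies and problem sizes

`scripts/acceptance.py` reruns all validation studies from scratch:
1000-signal spectral oracle comparison; suppression closed forms;
individualized-band recovery (100 seeds per planted peak at 8.5–12.5 Hz,
three 60 s videos per seed) and fallback on featureless spectra
(100 seeds, nine 120 s videos per seed — the detector's intended
averaging scale); exhaustive change-detection enumeration to length 6
plus 1000 invariance fuzz cases; 200 recovery and 200 null simulations
of the video-level model at 40 participants × 9 videos; 500 pure-noise
ladder simulations; and a byte-level determinism check of two identical
pipeline runs.  Unit tests run the same studies at reduced sizes.

## Numerical choices and degenerate inputs

- Variance-ratio searches run Nelder-Mead from two starts
  (moderate and near-zero variance); ratios are optimized on the log
  scale and clipped at e^±30, so boundary (singular) fits are reported
  with a flag rather than failing.
- GLMM inner Newton uses step-halving and warm starts across outer
  evaluations; extreme coefficients trigger a quasi-separation warning.
- Zero-variance rating series give missing EA; zero/negative band
  powers give missing S; empty kept-epoch sets propagate as missing
  trials and are logged, never raised mid-pipeline.
- All generators are pure functions of (config, seed) via spawned
  seed sequences, so studies are bit-identical across runs and
  platforms with the same numpy version.

## Known limitations

- No time–frequency decompositions, source localization, channels
  beyond C3/C4/O1/O2, or random slopes (intercepts only, matching the
  target analysis).
- Kenward–Roger small-sample F tests are not implemented; the ladder
  is asymptotic LRT (adequate at the simulated sizes, as the null
  calibration shows, but anticonservative for very small samples).
- EDF files can be read (via mne) but not written; the on-disk EEG
  format is the documented CSV dialect.
- The Laplace approximation can bias variance components for binary
  outcomes with few clusters; agreement with glmer is exact only in
  the sense that both use the same approximation.
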