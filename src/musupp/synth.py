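"""Synthetic study generator.

Emulates the statistical structure of a naturalistic empathic-accuracy
EEG study so the whole pipeline is testable without any real data:

* ``targets`` narrate videos of 105-228 s; their self-reported affect is
  a bounded piecewise-constant-plus-ramp trace on a 0-100 slider
  sampled every 0.5 s, with Poisson-spaced change points so increase,
  decrease and maintain epochs all occur;
* ``observers`` produce a fidelity-weighted, lagged, noise-corrupted
  copy of the target trace - fidelity controls the true accuracy the
  pipeline must recover;
* EEG at C3/C4/O1/O2 is 1/f-shaped Gaussian noise plus a band-limited
  oscillation at each participant's own peak frequency (mu centrally,
  alpha occipitally, one individual rhythm frequency per participant);
  oscillation amplitude on C4 decreases with a per-epoch "engagement"
  latent, occipital amplitude with a separate "visual attention"
  latent, and a 5 s fixation segment with zero engagement precedes
  stimulus onset;
* a per-trial coupling chains engagement -> predicted C4 suppression ->
  observer fidelity, so mean C4 suppression relates to empathic
  accuracy with a planted slope (``coupling_beta``).

Every latent quantity (mu peak, engagement traces, fidelities, the
coupling) is retained in ``StudyDataset.truth`` for recovery tests, and
all generators are pure functions of (config, seed).

For parameter-recovery simulations of the mixed models themselves the
module also provides :func:`simulate_trial_table` and
:func:`simulate_epoch_table`, which draw directly from the fitted
model's generative form with known coefficients - the right level for
checking coverage and type-I error of the fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    ANALYSIS_CHANNELS,
    CONDITIONS,
    EPOCH_LENGTH_S,
    EEGRecording,
    RatingSeries,
)

# Condition-level latent means.  Engagement (sensorimotor) is highest
# with both channels present; visual attention is highest for silent
# video; observer fidelity is highest when the narrative is audible.
COND_ENGAGEMENT = {"Audio-Video": 0.65, "Video-Only": 0.45, "Audio-Only": 0.35}
COND_VISUAL = {"Audio-Video": 0.60, "Video-Only": 0.70, "Audio-Only": 0.15}
COND_FIDELITY = {"Audio-Video": 0.70, "Video-Only": 0.40, "Audio-Only": 0.65}

#: oscillation amplitude (uV) and 1/f noise scale giving an in-band
#: power SNR of roughly 3:1 at the peak frequency on a 3 s epoch
OSC_AMP_UV = 4.0
NOISE_SD_UV = 10.0
#: maximum fractional amplitude attenuation at full engagement
ATTENUATION_MAX = 0.5


@dataclass
class GenerationConfig:
    """Study-level knobs for :func:`generate_study`.

    Defaults mirror the study design: 20 participants, 9 videos of
    105-228 s grouped into three counterbalanced sets, ratings every
    0.5 s, EEG at 1024 Hz with a 5 s pre-stimulus fixation.
    """

    n_participants: int = 20
    n_videos: int = 9
    video_duration_s: Optional[Sequence[float]] = None  # None -> draw 105-228 s
    rating_dt_s: float = 0.5
    eeg_fs_hz: float = 1024.0
    fixation_s: float = 5.0
    mu_peak_hz: Optional[float] = None  # None -> per-participant U(8.5, 12.5)
    coupling_beta: float = -0.9
    noise_sd: float = NOISE_SD_UV
    osc_amp: float = OSC_AMP_UV
    attenuation_max: float = ATTENUATION_MAX
    fidelity_noise_sd: float = 0.08
    engagement_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("mixed models need >= 2 participants")
        if self.n_videos % 3 != 0:
            raise ValueError("n_videos must be divisible by 3 (three sets)")
        per = EPOCH_LENGTH_S / self.rating_dt_s
        if abs(per - round(per)) > 1e-9:
            raise ValueError("rating_dt_s must divide the 3 s epoch length")
        if self.fixation_s <= 0 or self.rating_dt_s <= 0 or self.eeg_fs_hz <= 0:
            raise ValueError("durations and rates must be positive")
        if self.mu_peak_hz is not None and not (8.0 <= self.mu_peak_hz <= 13.0):
            raise ValueError("mu_peak_hz must lie in [8, 13]")


@dataclass
class StudyDataset:
    """A complete synthetic study plus the latent truth that made it."""

    design: pd.DataFrame                       # participant, video, condition, set_id
    targets: Dict[str, RatingSeries]
    observers: Dict[Tuple[str, str], RatingSeries]
    eeg: Dict[Tuple[str, str], EEGRecording]
    truth: dict
    config: GenerationConfig = field(repr=False, default=None)  # type: ignore


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def generate_target_rating(duration_s: float, dt: float = 0.5,
                           seed=None, video: Optional[str] = None) -> RatingSeries:
    """A target's affect trace: bounded piecewise-constant-plus-ramp.

    Segments with exponentially distributed lengths either hold the
    slider (exact equality -> maintain epochs), ramp linearly to a new
    level, or jump.  Values are clipped to [0, 100].
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    if n == 0:
        raise ValueError("duration shorter than one sample")
    values = np.empty(n)
    level = float(rng.uniform(30, 70))
    i = 0
    while i < n:
        seg = int(np.clip(round(rng.exponential(8.0) / dt), 3, 40))
        seg = min(seg, n - i)
        kind = rng.choice(["hold", "ramp", "jump"], p=[0.45, 0.35, 0.2])
        if kind == "hold":
            values[i:i + seg] = level
        elif kind == "ramp":
            new = level + rng.normal(0, 20)
            values[i:i + seg] = np.linspace(level, new, seg)
            level = new
        else:
            level = level + rng.normal(0, 25)
            values[i:i + seg] = level
        i += seg
    return RatingSeries(np.clip(values, 0, 100), dt_s=dt, role="target",
                        video=video)


def generate_observer_rating(target: RatingSeries, fidelity: float,
                             lag_s: float = 0.0, noise_sd: float = 0.0,
                             seed=None, participant: Optional[str] = None
                             ) -> RatingSeries:
    """Observer trace: fidelity-weighted, lagged, noisy copy of the target.

    ``fidelity=1, lag=0, noise=0`` reproduces the target exactly;
    ``fidelity=0`` yields a trace statistically independent of it (an
    independently generated pseudo-target).  Same length and dt as the
    target; clipped to [0, 100].
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    lag = int(round(lag_s / target.dt_s))
    if lag >= len(target):
        raise ValueError("lag longer than the series")
    rng = np.random.default_rng(seed)
    lagged = np.concatenate([np.full(lag, target.values[0]),
                             target.values[: len(target) - lag]])
    distract = generate_target_rating(target.duration_s, target.dt_s,
                                      seed=rng.integers(2 ** 31)).values
    obs = fidelity * lagged + (1.0 - fidelity) * distract
    if noise_sd > 0:
        obs = obs + rng.normal(0, noise_sd, size=obs.size)
    return RatingSeries(np.clip(obs, 0, 100), dt_s=target.dt_s, role="observer",
                        participant=participant, video=target.video)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def pink_noise(n: int, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """1/f-shaped Gaussian noise, standardized to the requested SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _amplitude_envelope(latent: np.ndarray, n_total: int, onset: int,
                        n_epoch: int, attenuation_max: float) -> np.ndarray:
    """Per-sample amplitude factor: 1 during fixation, per-epoch after."""
    env = np.ones(n_total)
    for i in range(latent.size):
        s = onset + i * n_epoch
        e = min(s + n_epoch, n_total)
        if s >= n_total:
            break
        env[s:e] = 1.0 - attenuation_max * latent[i]
    if onset + latent.size * n_epoch < n_total and latent.size:
        env[onset + latent.size * n_epoch:] = 1.0 - attenuation_max * latent[-1]
    return env


def generate_eeg(duration_s: float, fs: float, mu_peak_hz: float,
                 engagement: np.ndarray,
                 visual: Optional[np.ndarray] = None,
                 fixation_s: float = 5.0,
                 noise_sd: float = NOISE_SD_UV,
                 osc_amp: float = OSC_AMP_UV,
                 attenuation_max: float = ATTENUATION_MAX,
                 seed=None,
                 participant: Optional[str] = None,
                 video: Optional[str] = None) -> EEGRecording:
    """Four-channel synthetic EEG with engagement-modulated oscillations.

    ``engagement`` (and optionally ``visual``) are sampled on the 3 s
    epoch grid with values in [0, 1]; the oscillation amplitude on the
    central (occipital) channels is ``osc_amp * (1 - attenuation_max *
    latent)`` within each epoch, so higher engagement yields more
    negative suppression indices.  A fixation segment with latent 0
    precedes onset.  C4 carries the full engagement effect, C3 a
    third of it (the coupling under test is right-lateralized).
    """
    if fs < 60.0:
        raise ValueError("fs must be >= 60 Hz to support the 30 Hz low-pass")
    engagement = np.asarray(engagement, dtype=float)
    if engagement.ndim != 1 or np.any((engagement < 0) | (engagement > 1)):
        raise ValueError("engagement must be a 1-D array in [0, 1]")
    if visual is None:
        visual = np.zeros_like(engagement)
    visual = np.asarray(visual, dtype=float)

    rng = np.random.default_rng(seed)
    n_epoch = int(round(EPOCH_LENGTH_S * fs))
    onset = int(round(fixation_s * fs))
    n_total = onset + int(round(duration_s * fs))
    t = np.arange(n_total) / fs

    env_c4 = _amplitude_envelope(engagement, n_total, onset, n_epoch, attenuation_max)
    env_c3 = _amplitude_envelope(engagement, n_total, onset, n_epoch,
                                 attenuation_max / 3.0)
    env_occ = _amplitude_envelope(visual, n_total, onset, n_epoch, attenuation_max)

    chans = []
    for label, env in (("C3", env_c3), ("C4", env_c4),
                       ("O1", env_occ), ("O2", env_occ)):
        phase = rng.uniform(0, 2 * np.pi)
        osc = osc_amp * env * np.sin(2 * np.pi * mu_peak_hz * t + phase)
        chans.append(osc + pink_noise(n_total, rng, sd=noise_sd))
    return EEGRecording(np.vstack(chans), fs=fs,
                        channel_labels=list(ANALYSIS_CHANNELS),
                        onset_index=onset, fixation_s=fixation_s,
                        participant=participant, video=video)


# ---------------------------------------------------------------------------
# Whole studies
# ---------------------------------------------------------------------------

def make_design(n_participants: int, n_videos: int) -> pd.DataFrame:
    """Counterbalanced participant x video x condition table.

    Videos are grouped into three sets by index; the set-to-condition
    mapping rotates across participants, so each set appears in each
    condition equally often whenever n_participants is divisible by 3.
    """
    if n_videos % 3 != 0:
        raise ValueError("n_videos must be divisible by 3")
    per_set = n_videos // 3
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        for v in range(n_videos):
            set_id = v // per_set
            condition = CONDITIONS[(set_id + i) % 3]
            rows.append({"participant": pid, "video": f"V{v + 1}",
                         "condition": condition, "set_id": f"set{set_id + 1}"})
    return pd.DataFrame(rows)


def predicted_c4_suppression(engagement_mean: float,
                             attenuation_max: float = ATTENUATION_MAX,
                             band_snr: float = 3.0) -> float:
    """Closed-form expected C4 suppression at a mean engagement level.

    With oscillation band power P and noise band power N = P/band_snr,
    attenuating the amplitude by factor a scales oscillation power by
    a^2, so S = ln((a^2 P + N) / (P + N)).
    """
    a = 1.0 - attenuation_max * engagement_mean
    return float(np.log((a * a * band_snr + 1.0) / (band_snr + 1.0)))


def generate_study(config: GenerationConfig) -> StudyDataset:
    """Generate a full study: design, ratings, EEG and the latent truth.

    Deterministic given ``config.seed``: every trial draws from its own
    spawned random stream, so datasets are bit-identical across runs.
    """
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    design = make_design(config.n_participants, config.n_videos)
    videos = [f"V{v + 1}" for v in range(config.n_videos)]
    participants = sorted(design["participant"].unique())

    if config.video_duration_s is None:
        durations = {v: float(rng.integers(105, 229)) for v in videos}
    else:
        durations = {v: float(d) for v, d in zip(videos, config.video_duration_s)}

    targets = {
        v: generate_target_rating(durations[v], config.rating_dt_s,
                                  seed=root.spawn(1)[0], video=v)
        for v in videos
    }

    if config.mu_peak_hz is None:
        mu_peaks = {p: float(rng.uniform(8.5, 12.5)) for p in participants}
    else:
        mu_peaks = {p: config.mu_peak_hz for p in participants}

    observers: Dict[Tuple[str, str], RatingSeries] = {}
    eeg: Dict[Tuple[str, str], EEGRecording] = {}
    trial_truth = []
    for row in design.itertuples():
        p, v, cond = row.participant, row.video, row.condition
        trial_rng = np.random.default_rng(root.spawn(1)[0])
        n_epochs = int(durations[v] // EPOCH_LENGTH_S)
        e_trial = float(np.clip(
            trial_rng.normal(COND_ENGAGEMENT[cond], config.engagement_sd), 0, 1))
        engagement = np.clip(e_trial + trial_rng.normal(0, 0.05, n_epochs), 0, 1)
        vis_trial = float(np.clip(trial_rng.normal(COND_VISUAL[cond], 0.12), 0, 1))
        visual = np.clip(vis_trial + trial_rng.normal(0, 0.05, n_epochs), 0, 1)

        # coupling is within-condition: fidelity deviates from the condition
        # baseline in proportion to the trial's predicted C4 suppression
        s_pred = predicted_c4_suppression(float(engagement.mean()),
                                          config.attenuation_max)
        s_ref = predicted_c4_suppression(COND_ENGAGEMENT[cond],
                                         config.attenuation_max)
        fidelity = float(np.clip(
            COND_FIDELITY[cond] + config.coupling_beta * (s_pred - s_ref)
            + trial_rng.normal(0, config.fidelity_noise_sd), 0.02, 0.98))

        observers[(p, v)] = generate_observer_rating(
            targets[v], fidelity, lag_s=0.5, noise_sd=4.0,
            seed=trial_rng.integers(2 ** 31), participant=p)
        eeg[(p, v)] = generate_eeg(
            durations[v], config.eeg_fs_hz, mu_peaks[p], engagement,
            visual=visual, fixation_s=config.fixation_s,
            noise_sd=config.noise_sd, osc_amp=config.osc_amp,
            attenuation_max=config.attenuation_max,
            seed=trial_rng.integers(2 ** 31), participant=p, video=v)
        trial_truth.append({"participant": p, "video": v, "condition": cond,
                            "engagement_mean": float(engagement.mean()),
                            "visual_mean": float(visual.mean()),
                            "predicted_S_C4": s_pred, "fidelity": fidelity})

    truth = {"mu_peaks": mu_peaks, "coupling_beta": config.coupling_beta,
             "trials": pd.DataFrame(trial_truth),
             "durations": durations,
             "condition_engagement": dict(COND_ENGAGEMENT),
             "condition_fidelity": dict(COND_FIDELITY)}
    return StudyDataset(design=design, targets=targets, observers=observers,
                        eeg=eeg, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Model-level simulators (parameter recovery / calibration)
# ---------------------------------------------------------------------------

#: coefficient defaults on the scale of the printed video-level model
TRIAL_BETA_DEFAULTS = {"(Intercept)": 0.33, "S_C3": 0.0, "S_C4": -0.21,
                       "S_O1": 0.0, "S_O2": 0.0,
                       "condition[Video-Only]": -0.86,
                       "condition[Audio-Only]": -0.20}


def simulate_trial_table(n_participants: int = 40, n_videos: int = 9,
                         beta: Optional[dict] = None,
                         tau_participant: float = 0.01, tau_video: float = 0.04,
                         sigma2: float = 0.08,
                         s_mean: float = -0.3, s_sd: float = 0.3,
                         s_corr: float = 0.3, seed=None) -> pd.DataFrame:
    """Draw a TrialTable directly from the video-level model.

    Suppression means per channel are Gaussian with a common-factor
    correlation ``s_corr``; EA is the linear predictor plus crossed
    random intercepts and residual noise with the stated variances
    (defaults on the scale of the printed model: residual 0.08,
    video intercept 0.04).  Used for coverage / type-I simulations
    where the generative model must equal the fitted one.
    """
    rng = np.random.default_rng(seed)
    b = dict(TRIAL_BETA_DEFAULTS)
    if beta:
        b.update(beta)
    design = make_design(n_participants, n_videos)
    n = len(design)
    common = rng.standard_normal(n)
    S = {}
    for c in ("C3", "C4", "O1", "O2"):
        own = rng.standard_normal(n)
        S[f"S_{c}"] = s_mean + s_sd * (np.sqrt(s_corr) * common
                                       + np.sqrt(1 - s_corr) * own)
    df = design.copy()
    for k, v in S.items():
        df[k] = v
    bp = rng.normal(0, np.sqrt(tau_participant), n_participants)
    bv = rng.normal(0, np.sqrt(tau_video), n_videos)
    p_idx = pd.factorize(df["participant"], sort=True)[0]
    v_idx = pd.factorize(df["video"], sort=True)[0]
    eta = (b["(Intercept)"]
           + sum(b[f"S_{c}"] * df[f"S_{c}"].to_numpy() for c in CHANNEL_SHORT)
           + b["condition[Video-Only]"] * (df["condition"] == "Video-Only").to_numpy()
           + b["condition[Audio-Only]"] * (df["condition"] == "Audio-Only").to_numpy())
    df["EA"] = eta + bp[p_idx] + bv[v_idx] + rng.normal(0, np.sqrt(sigma2), n)
    return df


CHANNEL_SHORT = ("C3", "C4", "O1", "O2")

EPOCH_BETA_DEFAULTS = {"(Intercept)": -0.32, "S_C3": 0.0, "S_C4": -0.12,
                       "S_O1": 0.0, "S_O2": 0.0,
                       "condition[Video-Only]": -0.17,
                       "condition[Audio-Only]": -0.03}


def simulate_epoch_table(n_participants: int = 20, n_videos: int = 9,
                         epochs_per_trial: int = 40,
                         beta: Optional[dict] = None,
                         tau_participant: float = 0.09, tau_video: float = 0.03,
                         s_mean: float = -0.3, s_sd: float = 0.6,
                         seed=None) -> pd.DataFrame:
    """Draw an EpochTable from the epoch-level binomial model.

    Per-epoch suppression values are Gaussian; change-detection success
    is Bernoulli with logit equal to the linear predictor plus crossed
    random intercepts (defaults on the printed epoch-level scale).
    """
    from scipy.special import expit
    rng = np.random.default_rng(seed)
    b = dict(EPOCH_BETA_DEFAULTS)
    if beta:
        b.update(beta)
    design = make_design(n_participants, n_videos)
    rows = design.loc[design.index.repeat(epochs_per_trial)].reset_index(drop=True)
    rows["epoch_index"] = np.tile(np.arange(1, epochs_per_trial + 1), len(design))
    n = len(rows)
    for c in CHANNEL_SHORT:
        rows[f"S_{c}"] = rng.normal(s_mean, s_sd, n)
    bp = rng.normal(0, np.sqrt(tau_participant), n_participants)
    bv = rng.normal(0, np.sqrt(tau_video), n_videos)
    p_idx = pd.factorize(rows["participant"], sort=True)[0]
    v_idx = pd.factorize(rows["video"], sort=True)[0]
    eta = (b["(Intercept)"]
           + sum(b[f"S_{c}"] * rows[f"S_{c}"].to_numpy() for c in CHANNEL_SHORT)
           + b["condition[Video-Only]"] * (rows["condition"] == "Video-Only").to_numpy()
           + b["condition[Audio-Only]"] * (rows["condition"] == "Audio-Only").to_numpy()
           + bp[p_idx] + bv[v_idx])
    rows["success"] = (rng.uniform(size=n) < expit(eta)).astype(int)
    return rows
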