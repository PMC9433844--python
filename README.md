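# musupp

**Mu-rhythm suppression and empathic accuracy: an EEG/behavior analysis
pipeline.**

When people watch someone recount an emotional event and continuously
rate how that person feels, the accuracy of their inferences can be
linked to sensorimotor engagement measured by EEG: suppression of the
8–13 Hz mu rhythm over central sites (C3/C4), contrasted with occipital
alpha (O1/O2) as a visual-attention control.  `musupp` implements that
analysis end to end for researchers working with continuous
affect-rating paradigms:

- **Spectral**: 0.5–30 Hz filtering (24 dB/oct low-pass), ±100 µV
  artifact rejection, 3 s epochs, Hanning-windowed FFT on a 0.5 Hz
  grid, integrated band power, and the suppression index
  *S* = ln(*P*<sub>epoch</sub> / *P*<sub>baseline</sub>) against the
  pre-stimulus fixation baseline — with either the fixed 8–13 Hz band
  or individualized 2 Hz bands (peak ± 1 Hz, 9–11 Hz fallback when no
  peak stands out of the 1/f background).
- **Behavior**: video-level *empathic accuracy* (Pearson correlation of
  observer and target ratings on the 3 s epoch grid) and epoch-level
  *change-detection accuracy* (binary match of increase/decrease/
  maintain labels — scale-invariant and memory-less).
- **Models**: linear and binomial mixed models with crossed random
  intercepts for participant and video, a four-step hierarchical
  ladder (null → +suppression → +condition → +interaction, compared by
  likelihood-ratio tests), Bonferroni-corrected condition contrasts
  (*m* = 3), and an optional 2 SD outlier rule.  Estimates are
  cross-checked against `lme4` in the test suite.
- **Synthetic studies**: a generator that emulates the full study
  structure (counterbalanced conditions, 105–228 s videos, 0.5 s
  slider ratings, 1/f EEG with engagement-modulated oscillations and a
  planted suppression→accuracy coupling) so every stage is testable
  without any real data.

## Worked example

Simulate a small study and run the full chain from the shell:

```
$ musupp simulate --out study --n-participants 6 --n-videos 9 --fs 256 --seed 7
wrote 54 trials under study
$ musupp run --interaction C4_only --notch 0 --seed 7 study
run complete -> study/out
$ musupp report study/out
```

The report starts with the video-level model (this is real output from
the commands above):

```
== Video-level model: empathic accuracy ==
gaussian mixed model (REML)

                         beta      se  ci_low  ci_high    stat       p
(Intercept)            0.6458  0.1553  0.3333   0.9582  4.1576  0.0001
S_C3                  -0.1782  0.1538 -0.4876   0.1313 -1.1583  0.2526
S_C4                  -0.2126  0.1506 -0.5155   0.0903 -1.4118  0.1646
S_O1                  -0.0443  0.1452 -0.3365   0.2478 -0.3054  0.7614
S_O2                   0.1462  0.1129 -0.0810   0.3734  1.2946  0.2018
condition[Video-Only] -0.3191  0.1021 -0.5244  -0.1137 -3.1259  0.0030
condition[Audio-Only] -0.0046  0.1205 -0.2470   0.2378 -0.0383  0.9696

Random effects
  sigma^2        0.0861
  tau00 participant 0.0034
  tau00 video       0.0714
  ICC            0.4647
N  6 participants, 9 videos
Observations   54
```

Read it as: each unit of extra C4 suppression (more negative *S*, i.e.
stronger sensorimotor engagement) goes with a −0.21 change in empathic
accuracy — the planted negative coupling, recovered with the expected
sign though not significant at this tiny n — while accuracy is highest
in the Audio-Video and Audio-Only conditions (the narrative carries
most of the information; the Video-Only deficit of −0.32 is
significant).  The ladder and Bonferroni contrasts that follow in the
report quantify each block's contribution, and the epoch-level
binomial model repeats the analysis for change detection.  All tables
are also written as tidy CSVs with provenance headers, alongside a
machine-readable ledger of every dropped epoch and trial.

The same pipeline is available as a library:

```python
from musupp import (GenerationConfig, generate_study, suppression_table,
                    trial_means, accuracy_tables, fit_video_level)

study = generate_study(GenerationConfig(n_participants=6, eeg_fs_hz=256, seed=7))
supp = suppression_table(study.eeg, study.design)
ea, cd = accuracy_tables(study.observers.values(), study.targets, study.design)
trial = trial_means(supp).merge(ea, on=["participant", "video", "condition"])
print(fit_video_level(trial).summary())
```

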