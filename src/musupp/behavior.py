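"""Behavioral accuracy scores from continuous affect ratings.

Two measures are computed from target/observer rating pairs, both on
the 3 s epoch grid that matches the EEG analysis:

* **Empathic accuracy (EA)** - the Pearson correlation between the
  observer's and the target's epoch-averaged ratings for one video.
* **Change-detection accuracy** - per epoch (from the second epoch on),
  a binary success flag: did the observer's direction of change
  (increase / decrease / maintain vs the previous epoch) match the
  target's?  The measure is scale-invariant (direction only, never
  magnitude) and memory-less (each epoch is compared only to the one
  before it).
"""

from __future__ import annotations

from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import EPOCH_LENGTH_S, RatingSeries

INCREASE, DECREASE, MAINTAIN = "increase", "decrease", "maintain"


def epoch_average(r: RatingSeries, epoch_length_s: float = EPOCH_LENGTH_S) -> np.ndarray:
    """Mean rating per 3 s window; trailing partial window dropped.

    Mirrors the EEG floor rule: a 27 s series at dt=0.5 yields 9 epochs
    of 6 samples each.
    """
    per = epoch_length_s / r.dt_s
    if abs(per - round(per)) > 1e-9:
        raise ValueError(f"dt={r.dt_s}s does not divide the {epoch_length_s}s epoch")
    per = int(round(per))
    n_epochs = len(r) // per
    if n_epochs == 0:
        raise ValueError("series shorter than one epoch")
    return r.values[: n_epochs * per].reshape(n_epochs, per).mean(axis=1)


def empathic_accuracy(obs: np.ndarray, targ: np.ndarray) -> float:
    """Pearson correlation of epoch means; NaN if either side is constant."""
    obs = np.asarray(obs, dtype=float)
    targ = np.asarray(targ, dtype=float)
    if obs.shape != targ.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {targ.shape}")
    if obs.size < 2 or np.ptp(obs) == 0 or np.ptp(targ) == 0:
        return float("nan")
    return float(np.corrcoef(obs, targ)[0, 1])


def classify_changes(epoch_means: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """Direction of change per epoch relative to the previous one.

    Returns an array of length ``n_epochs - 1``: label t (for epoch
    t+1) is ``increase`` if mean rose by more than ``epsilon``,
    ``decrease`` if it fell by more than ``epsilon``, else ``maintain``.
    With ``epsilon=0`` the labels are invariant under any strictly
    increasing transform of the rating scale.  The first epoch has no
    label (there is no previous epoch).
    """
    epoch_means = np.asarray(epoch_means, dtype=float)
    if epoch_means.size < 2:
        raise ValueError("need at least two epochs to classify changes")
    d = np.diff(epoch_means)
    out = np.full(d.shape, MAINTAIN, dtype=object)
    out[d > epsilon] = INCREASE
    out[d < -epsilon] = DECREASE
    return out


def change_detection(obs_cat: np.ndarray, targ_cat: np.ndarray) -> np.ndarray:
    """Binary success per epoch: 1 iff the two labels are identical."""
    obs_cat = np.asarray(obs_cat, dtype=object)
    targ_cat = np.asarray(targ_cat, dtype=object)
    if obs_cat.shape != targ_cat.shape:
        raise ValueError("label sequences differ in length")
    return (obs_cat == targ_cat).astype(int)


# ---------------------------------------------------------------------------
# Study-level tables
# ---------------------------------------------------------------------------

def accuracy_tables(
    observers: Iterable[RatingSeries],
    targets: dict,
    design: Optional[pd.DataFrame] = None,
    epsilon: float = 0.0,
    epoch_length_s: float = EPOCH_LENGTH_S,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """EA and change-detection tables for a whole study.

    Parameters
    ----------
    observers
        One observer RatingSeries per (participant, video) trial.
    targets
        Mapping video id -> target RatingSeries.
    design
        Optional ``participant, video, condition`` table used to attach
        the viewing condition to each row.

    Returns
    -------
    ea : DataFrame with columns ``participant, video, condition, EA, n_epochs``.
    cd : DataFrame with columns ``participant, video, condition,
         epoch_index, success`` - one row per epoch from the second
         epoch onward (``epoch_index`` starts at 1).
    """
    cond = {}
    if design is not None:
        cond = {(r.participant, r.video): r.condition for r in design.itertuples()}
    ea_rows, cd_rows = [], []
    for obs in observers:
        targ = targets[obs.video]
        if len(obs) != len(targ):
            raise ValueError(f"observer/target length mismatch for video {obs.video}")
        om = epoch_average(obs, epoch_length_s)
        tm = epoch_average(targ, epoch_length_s)
        c = cond.get((obs.participant, obs.video))
        ea_rows.append({"participant": obs.participant, "video": obs.video,
                        "condition": c, "EA": empathic_accuracy(om, tm),
                        "n_epochs": om.size})
        succ = change_detection(classify_changes(om, epsilon),
                                classify_changes(tm, epsilon))
        for t, s in enumerate(succ, start=1):
            cd_rows.append({"participant": obs.participant, "video": obs.video,
                            "condition": c, "epoch_index": t, "success": int(s)})
    ea = pd.DataFrame(ea_rows, columns=["participant", "video", "condition",
                                        "EA", "n_epochs"])
    cd = pd.DataFrame(cd_rows, columns=["participant", "video", "condition",
                                        "epoch_index", "success"])
    return ea, cd


def score_correlation(ea: pd.DataFrame, cd: pd.DataFrame,
                      alpha: float = 0.05) -> dict:
    """Correlation of EA with per-trial mean change-detection rate.

    Matches trials on (participant, video); returns the Pearson r, its
    confidence interval and p-value.  With fewer than 3 matched trials,
    or when either score is constant, the correlation is undefined and
    returned as NaN.
    """
    rate = (cd.groupby(["participant", "video"], sort=True)["success"]
            .mean().rename("cd_rate").reset_index())
    merged = ea.merge(rate, on=["participant", "video"]).dropna(subset=["EA", "cd_rate"])
    if len(merged) < 3:
        raise ValueError("need at least 3 matched trials")
    x, y = merged["EA"].to_numpy(), merged["cd_rate"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "ci": (float("nan"), float("nan")),
                "p": float("nan"), "n": len(merged)}
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return {"r": float(res.statistic), "ci": (float(ci.low), float(ci.high)),
            "p": float(res.pvalue), "n": len(merged)}
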