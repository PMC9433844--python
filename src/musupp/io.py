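"""Readers and writers for the on-disk study formats.

All formats are plain text so a study round-trips without binary
dependencies:

* EEG: wide CSV ``time_s, C3, C4, O1, O2`` (microvolts) plus a sidecar
  ``<stem>.meta.json`` carrying fs, onset_index, fixation_s and ids.
  EDF reading is available when :mod:`mne` is installed.
* Ratings: long CSV ``participant, video, role, time_s, value``
  (targets have an empty participant field).
* Design: CSV ``participant, video, condition, set_id``.
* Result tables are tidy CSVs with a provenance comment header
  (package version, seed, config hash); readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .types import EEGRecording, RatingSeries

FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def write_eeg_csv(rec: EEGRecording, path) -> Path:
    """Write one recording as wide CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    t = np.arange(rec.n_times) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for i, c in enumerate(rec.channel_labels):
        df[c] = rec.samples[i]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {"fs": rec.fs, "onset_index": int(rec.onset_index),
            "fixation_s": rec.fixation_s, "participant": rec.participant,
            "video": rec.video, "channels": list(rec.channel_labels)}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_eeg_csv(path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    df = pd.read_csv(path)
    chans = meta["channels"]
    missing = [c for c in chans if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channel column(s) {missing}")
    return EEGRecording(df[chans].to_numpy().T, fs=float(meta["fs"]),
                        channel_labels=chans,
                        onset_index=int(meta["onset_index"]),
                        fixation_s=float(meta["fixation_s"]),
                        participant=meta.get("participant"),
                        video=meta.get("video"))


def read_edf(path, fixation_s: float = 5.0,
             onset_s: Optional[float] = None) -> EEGRecording:
    """Read an EDF recording via mne (optional dependency).

    ``onset_s`` defaults to ``fixation_s`` (recording starts at
    fixation).  Voltages are converted from volts to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package "
                          "(pip install musupp[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6
    onset = float(fixation_s if onset_s is None else onset_s)
    return EEGRecording(data, fs=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names),
                        onset_index=int(round(onset * raw.info["sfreq"])),
                        fixation_s=fixation_s)


# ---------------------------------------------------------------------------
# Ratings and design
# ---------------------------------------------------------------------------

def write_ratings_csv(targets: Dict[str, RatingSeries],
                      observers: Dict[Tuple[str, str], RatingSeries],
                      path) -> Path:
    rows = []
    for v, r in sorted(targets.items()):
        for i, val in enumerate(r.values):
            rows.append(("", v, "target", i * r.dt_s, val))
    for (p, v), r in sorted(observers.items()):
        for i, val in enumerate(r.values):
            rows.append((p, v, "observer", i * r.dt_s, val))
    df = pd.DataFrame(rows, columns=["participant", "video", "role",
                                     "time_s", "value"])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.3f")
    return path


def read_ratings_csv(path) -> Tuple[Dict[str, RatingSeries],
                                    Dict[Tuple[str, str], RatingSeries]]:
    df = pd.read_csv(path, keep_default_na=False, comment="#")
    targets: Dict[str, RatingSeries] = {}
    observers: Dict[Tuple[str, str], RatingSeries] = {}
    for (p, v, role), g in df.groupby(["participant", "video", "role"], sort=True):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"{path}: series {(p, v, role)} too short")
        dt = float(np.median(np.diff(t)))
        if not np.allclose(np.diff(t), dt, atol=1e-6):
            raise ValueError(f"{path}: non-uniform sampling for {(p, v, role)}")
        series = RatingSeries(g["value"].to_numpy(float), dt_s=dt, role=role,
                              participant=p or None, video=v)
        if role == "target":
            targets[v] = series
        else:
            observers[(p, v)] = series
    return targets, observers


def write_design_csv(design: pd.DataFrame, path) -> Path:
    path = Path(path)
    design.to_csv(path, index=False)
    return path


def read_design_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"participant", "video", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table lacks columns {sorted(missing)}")
    return df


def write_truth_json(truth: dict, path) -> Path:
    path = Path(path)
    out = dict(truth)
    if isinstance(out.get("trials"), pd.DataFrame):
        out["trials"] = out["trials"].to_dict(orient="records")
    path.write_text(json.dumps(out, indent=1, sort_keys=True, default=float))
    return path


def read_truth_json(path) -> dict:
    truth = json.loads(Path(path).read_text())
    if isinstance(truth.get("trials"), list):
        truth["trials"] = pd.DataFrame(truth["trials"])
    return truth


# ---------------------------------------------------------------------------
# Result tables with provenance
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config: Optional[dict] = None,
                seed: Optional[int] = None) -> Path:
    """Write a tidy CSV with a provenance comment header."""
    path = Path(path)
    header = [f"# musupp {__version__}"]
    if config is not None:
        header.append(f"# config_hash={config_hash(config)}")
    if seed is not None:
        header.append(f"# seed={seed}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
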