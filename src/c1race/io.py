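"""File formats: portable epochs, BrainVision triplets, tables, configs.

The portable epoch format is a directory holding a raw little-endian
float32 array (``data.f32``, C order, trials × channels × samples), a JSON
sidecar (``meta.json``: shape, sampling rate, first sample time, channel
names) and the trial table (``trials.csv``).  It is inspectable with any
language and round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .epochs import EpochSet

_DATA_FILE = "data.f32"
_META_FILE = "meta.json"
_TRIALS_FILE = "trials.csv"


def write_epochs(epochs: EpochSet, path) -> Path:
    """Write an epoch set in the portable format; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(epochs.data, dtype="<f4")
    data.tofile(path / _DATA_FILE)
    meta = {
        "shape": list(data.shape),
        "srate": epochs.srate,
        "tmin_ms": float(epochs.times[0]),
        "channels": list(epochs.channel_names),
        "dtype": "<f4",
        "order": "C",
    }
    (path / _META_FILE).write_text(json.dumps(meta, indent=2, sort_keys=True))
    epochs.trial_table.to_csv(path / _TRIALS_FILE, index=False)
    return path


def read_epochs(path, format: str = "portable") -> EpochSet:
    """Read an epoch set (``format`` is 'portable' or 'brainvision')."""
    if format == "portable":
        return _read_portable(path)
    if format == "brainvision":
        return read_brainvision_epochs(path)
    raise ValueError(f"unknown format {format!r}")


def _read_portable(path) -> EpochSet:
    path = Path(path)
    meta = json.loads((path / _META_FILE).read_text())
    shape = tuple(meta["shape"])
    data = np.fromfile(path / _DATA_FILE, dtype=meta.get("dtype", "<f4"))
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"malformed portable epochs: {data.size} values for shape {shape}")
    data = data.reshape(shape)
    trials = pd.read_csv(path / _TRIALS_FILE)
    if len(trials) != shape[0]:
        raise ValueError(
            f"trial table has {len(trials)} rows for {shape[0]} trials")
    srate = float(meta["srate"])
    times = meta["tmin_ms"] + np.arange(shape[2]) * 1000.0 / srate
    return EpochSet(data=data, times=times,
                    channel_names=tuple(meta["channels"]),
                    trial_table=trials, srate=srate)


def read_brainvision_epochs(
    vhdr_path,
    trial_table: pd.DataFrame | None = None,
    tmin_ms: float = -100.0,
    tmax_ms: float = 300.0,
    known_channels=None,
) -> EpochSet:
    """Epoch a BrainVision triplet (.vhdr/.eeg/.vmrk) around its stimulus
    markers.

    Requires :mod:`mne`.  Stimulus annotations become one epoch each; the
    caller supplies the matching trial table (or a minimal one is built from
    the marker descriptions).  Channel names are checked against
    ``known_channels`` when given.
    """
    import mne  # deferred: only needed for this reader

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    if known_channels is not None:
        unknown = set(raw.ch_names) - set(known_channels)
        if unknown:
            raise ValueError(
                f"unknown channel(s) in BrainVision file: {sorted(unknown)}")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    stim_ids = {k: v for k, v in event_id.items()
                if k.startswith("Stimulus") or k.startswith("S")}
    if not stim_ids:
        stim_ids = event_id
    events = events[np.isin(events[:, 2], list(stim_ids.values()))]
    epo = mne.Epochs(raw, events, tmin=tmin_ms / 1000.0, tmax=tmax_ms / 1000.0,
                     baseline=None, preload=True, verbose="error")
    data = epo.get_data() * 1e6  # volts → µV
    times = epo.times * 1000.0
    if trial_table is None:
        inv = {v: k for k, v in stim_ids.items()}
        trial_table = pd.DataFrame({
            "participant": "unknown",
            "condition": [inv.get(c, str(c)) for c in epo.events[:, 2]],
            "visual_field": "none", "visual_side": "none",
            "sound_side": "none", "is_target": False,
            "response_latency_ms": np.nan,
        })
    if len(trial_table) != data.shape[0]:
        raise ValueError(
            f"trial table has {len(trial_table)} rows for "
            f"{data.shape[0]} epochs")
    return EpochSet(data=data, times=times, channel_names=tuple(epo.ch_names),
                    trial_table=trial_table.reset_index(drop=True),
                    srate=float(raw.info["sfreq"]))


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
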