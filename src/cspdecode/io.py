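"""Epoch container I/O and optional continuous-EEG adapters.

The on-disk epoch container is a pair of files sharing a stem:

* ``<stem>.npy``  — the ``trials x channels x samples`` float64 array in
  NumPy's standard .npy layout;
* ``<stem>.json`` — a sidecar with ``fs``, ``labels``, ``window`` and
  ``channel_names``.

Reading EDF/GDF continuous recordings requires the optional ``mne``
dependency (``pip install cspdecode[eeg-io]``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import EpochSet, RawRecording
from .errors import DataError

__all__ = ["save_epochs", "load_epochs", "read_raw_edf", "read_raw_gdf"]


def save_epochs(epochs: EpochSet, stem) -> tuple[Path, Path]:
    """Write ``<stem>.npy`` + ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    npy_path = stem.with_suffix(".npy")
    json_path = stem.with_suffix(".json")
    np.save(npy_path, epochs.data)
    sidecar = {
        "fs": epochs.fs,
        "labels": epochs.labels.tolist(),
        "window": list(epochs.window),
        "channel_names": list(epochs.channel_names),
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return npy_path, json_path


def load_epochs(stem) -> EpochSet:
    """Read an epoch container written by :func:`save_epochs`."""
    stem = Path(stem)
    npy_path = stem.with_suffix(".npy")
    json_path = stem.with_suffix(".json")
    if not npy_path.exists() or not json_path.exists():
        raise DataError(f"missing container file(s) for stem {stem}")
    data = np.load(npy_path)
    sidecar = json.loads(json_path.read_text())
    for key in ("fs", "labels", "window", "channel_names"):
        if key not in sidecar:
            raise DataError(f"sidecar {json_path} missing key {key!r}")
    return EpochSet(
        data=data,
        labels=np.asarray(sidecar["labels"], dtype=int),
        fs=float(sidecar["fs"]),
        window=tuple(sidecar["window"]),
        channel_names=list(sidecar["channel_names"]),
    )


def _read_raw_mne(path, reader_name: str, label_map: dict[str, int]) -> RawRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF/GDF requires the optional 'mne' dependency "
            "(pip install cspdecode[eeg-io])"
        ) from exc
    reader = getattr(mne.io, reader_name)
    raw = reader(path, preload=True, verbose="error")
    events = []
    onsets = raw.annotations.onset
    descriptions = raw.annotations.description
    for onset_s, desc in zip(onsets, descriptions):
        if desc in label_map:
            events.append((int(round(onset_s * raw.info["sfreq"])), label_map[desc]))
    return RawRecording(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=events,
    )


def read_raw_edf(path, label_map: dict[str, int]) -> RawRecording:
    """EDF adapter: annotations in ``label_map`` become +/-1 events."""
    return _read_raw_mne(path, "read_raw_edf", label_map)


def read_raw_gdf(path, label_map: dict[str, int]) -> RawRecording:
    """GDF adapter: annotations in ``label_map`` become +/-1 events."""
    return _read_raw_mne(path, "read_raw_gdf", label_map)
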