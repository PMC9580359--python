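"""Epoched EEG container and its plain-text on-disk form.

An :class:`EpochSet` holds a trials x channels x samples tensor of epoched
EEG (microvolts), one class label per trial (at most two distinct classes),
the sampling rate, channel names, and ``t0`` — the time of the first sample
relative to trial onset in milliseconds.

On-disk container (text only, documented bit-exactly)
-----------------------------------------------------
A directory with two files:

``meta.json``
    ``{"fs": float, "t0_ms": float, "n_trials": int, "n_channels": int,
    "n_samples": int, "channel_names": [str, ...], "labels": [str, ...]}``

``data.txt``
    The tensor reshaped to ``(n_trials * n_channels, n_samples)``, row
    ``i = trial * n_channels + channel``, written by ``numpy.savetxt`` with
    format ``%.10g``, space-delimited, one row per line.

Optional EDF/GDF ingestion (BCI Competition IV 2a/2b) requires ``mne``,
which is not a dependency; the readers raise ImportError when it is absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidDataError

__all__ = ["EpochSet", "save_epochs", "load_epochs", "read_edf_epochs", "read_gdf_epochs"]


@dataclass
class EpochSet:
    """Labeled epoched EEG: ``data`` is trials x channels x samples (uV)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    t0: float = 0.0  # ms of first sample relative to trial onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise InvalidDataError(
                f"data must be trials x channels x samples, got ndim={self.data.ndim}"
            )
        n_trials = self.data.shape[0]
        if n_trials < 1 or self.data.shape[1] < 1:
            raise InvalidDataError("need at least one trial and one channel")
        if self.labels.shape != (n_trials,):
            raise InvalidDataError(
                f"labels shape {self.labels.shape} does not match {n_trials} trials"
            )
        if len(np.unique(self.labels)) > 2:
            raise InvalidDataError("EpochSet supports at most two classes")
        if not self.fs > 0:
            raise InvalidDataError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise InvalidDataError("channel_names length does not match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Sorted distinct labels."""
        return np.unique(self.labels)

    @property
    def t_end(self) -> float:
        """Time just past the last sample (ms relative to onset)."""
        return self.t0 + self.n_samples / self.fs * 1000.0

    def copy_with(self, data: np.ndarray, t0: float | None = None) -> "EpochSet":
        """New EpochSet sharing labels/metadata with replaced data tensor."""
        return EpochSet(
            data=data,
            labels=self.labels.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            t0=self.t0 if t0 is None else t0,
        )

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EpochSet":
        """Select trials by index, preserving order."""
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            t0=self.t0,
        )


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write the plain-text container described in the module docstring."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": float(epochs.fs),
        "t0_ms": float(epochs.t0),
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
        "channel_names": list(epochs.channel_names),
        "labels": [str(x) for x in epochs.labels],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    flat = epochs.data.reshape(epochs.n_trials * epochs.n_channels, epochs.n_samples)
    np.savetxt(path / "data.txt", flat, fmt="%.10g")


def load_epochs(path: str | Path) -> EpochSet:
    """Read the plain-text container written by :func:`save_epochs`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    flat = np.loadtxt(path / "data.txt", ndmin=2)
    data = flat.reshape(meta["n_trials"], meta["n_channels"], meta["n_samples"])
    return EpochSet(
        data=data,
        labels=np.asarray(meta["labels"]),
        fs=meta["fs"],
        channel_names=list(meta["channel_names"]),
        t0=meta["t0_ms"],
    )


def _read_mne_epochs(path, event_map, tmin_s, tmax_s, reader_name):
    try:
        import mne  # noqa: F401  (optional dependency)
    except ImportError as exc:  # pragma: no cover - mne not installed in CI
        raise ImportError(
            f"{reader_name} requires the optional dependency 'mne' "
            "(pip install mne); it is never needed for the bundled tests"
        ) from exc
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    picks = {code: label for code, label in event_map.items() if code in event_id}
    ev_id = {label: event_id[code] for code, label in picks.items()}
    ep = mne.Epochs(
        raw, events, event_id=ev_id, tmin=tmin_s, tmax=tmax_s,
        baseline=None, preload=True, verbose="error",
    )
    inv = {v: k for k, v in ev_id.items()}
    labels = np.asarray([inv[e] for e in ep.events[:, 2]])
    return EpochSet(
        data=ep.get_data() * 1e6,  # Volts -> uV
        labels=labels,
        fs=float(ep.info["sfreq"]),
        channel_names=list(ep.ch_names),
        t0=tmin_s * 1000.0,
    )


def read_edf_epochs(path: str | Path, event_map: dict[str, str],
                    tmin_s: float = 0.0, tmax_s: float = 7.0) -> EpochSet:
    """Epoch an EDF recording (e.g. BCI Competition IV 2b) around cue events.

    ``event_map`` maps annotation codes to class labels, e.g.
    ``{"769": "left", "770": "right"}``. Requires the optional ``mne``.
    """
    return _read_mne_epochs(path, event_map, tmin_s, tmax_s, "read_edf_epochs")


def read_gdf_epochs(path: str | Path, event_map: dict[str, str],
                    tmin_s: float = 0.0, tmax_s: float = 7.0) -> EpochSet:
    """Epoch a GDF recording (e.g. BCI Competition IV 2a). Requires ``mne``."""
    return _read_mne_epochs(path, event_map, tmin_s, tmax_s, "read_gdf_epochs")
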