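"""Labeled multichannel EEG epochs and their on-disk format.

An epoch is one trial: a ``channels x samples`` array in microvolts, a
sampling rate, a class label and channel names.  On disk an epoch is a
whitespace-delimited numeric matrix (rows = channels) next to a JSON
sidecar ``<stem>.json`` holding ``{fs, label, channel_names}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class EEGEpoch:
    """One labeled EEG trial.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Class identifier (e.g. ``"left_hand"``).
    channel_names : list of str
        One name per row of ``data``.
    """

    data: np.ndarray
    fs: float
    label: str
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "EEGEpoch":
        """New epoch with the same metadata but different samples."""
        return EEGEpoch(data=data, fs=self.fs, label=self.label,
                        channel_names=list(self.channel_names))


def save_epoch(epoch: EEGEpoch, path: str | Path) -> None:
    """Write ``<path>`` (delimited matrix) and ``<path stem>.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, epoch.data)
    meta = {"fs": epoch.fs, "label": epoch.label,
            "channel_names": list(epoch.channel_names)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epoch(path: str | Path) -> EEGEpoch:
    """Read an epoch written by :func:`save_epoch`."""
    path = Path(path)
    data = np.atleast_2d(np.loadtxt(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    return EEGEpoch(data=data, fs=float(meta["fs"]), label=str(meta["label"]),
                    channel_names=list(meta["channel_names"]))


def save_dataset(epochs: list[EEGEpoch], out_dir: str | Path,
                 manifest_extra: dict | None = None) -> Path:
    """Write every epoch as ``epoch_%04d.txt`` plus a ``manifest.json``.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, ep in enumerate(epochs):
        name = f"epoch_{i:04d}.txt"
        save_epoch(ep, out_dir / name)
        names.append(name)
    manifest = {"n_epochs": len(epochs), "files": names}
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_dataset(out_dir: str | Path) -> list[EEGEpoch]:
    """Read a dataset directory written by :func:`save_dataset`."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return [load_epoch(out_dir / name) for name in manifest["files"]]


def read_edf_epochs(path: str | Path, epoch_seconds: float,
                    label: str = "unknown") -> list[EEGEpoch]:
    """Slice a continuous EDF recording into fixed-length epochs.

    Requires the optional ``mne`` dependency.  Records are read once,
    converted to microvolts and cut into non-overlapping windows of
    ``epoch_seconds``; a trailing partial window is dropped.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    win = int(round(epoch_seconds * fs))
    out = []
    for start in range(0, data.shape[1] - win + 1, win):
        out.append(EEGEpoch(data=data[:, start:start + win], fs=fs,
                            label=label, channel_names=list(raw.ch_names)))
    return out
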