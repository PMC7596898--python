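"""Loading, segmenting and band-filtering multichannel EEG.

The containers here mirror how two-class motor-imagery BCI recordings are
distributed: one long continuous multichannel signal (channels x samples,
microvolts), a sampling rate, and a marker table of cue onsets with class
labels (1 = right hand, 2 = right foot).  Trials are cut as fixed-length
epochs anchored at each cue onset and band-filtered to the mu-rhythm range
before spatial filtering.

Supported on-disk layouts: MATLAB MAT-files (v5 via scipy.io, v7.3 via
h5py), plain HDF5 with ``/signal``, ``/fs`` and ``/markers`` datasets, and
CSV (channels as columns) with a JSON sidecar carrying ``fs`` and markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.io
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EEGRecording",
    "Epoch",
    "EpochSet",
    "FormatError",
    "ValidationError",
    "load_recording",
    "save_recording",
    "segment_epochs",
    "bandpass",
    "save_epochs",
    "load_epochs",
]


class FormatError(ValueError):
    """A container file is missing a required field or uses an unknown layout."""


class ValidationError(ValueError):
    """Loaded data violates a structural invariant (shape, finiteness, bounds)."""


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with trial-cue markers.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Continuous signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per signal row.
    markers : list of (int, int)
        ``(onset_sample, class_label)`` trial cues; onsets are 0-based.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    markers: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError(
                f"signal must be 2-D (channels x samples), got shape {self.signal.shape}"
            )
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.signal.shape[0])]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        bad = np.argwhere(~np.isfinite(self.signal))
        if bad.size:
            ch, s = bad[0]
            raise ValidationError(
                f"non-finite sample at channel {ch}, sample {s}"
            )
        self.markers = [(int(o), int(c)) for o, c in self.markers]
        n = self.signal.shape[1]
        for i, (onset, _label) in enumerate(self.markers):
            if onset < 0 or onset >= n:
                raise ValidationError(
                    f"marker {i} onset {onset} outside signal of {n} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class Epoch:
    """One cue-aligned trial: channels x T samples with a class label."""

    data: np.ndarray
    label: int
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("epoch data must be 2-D (channels x T)")
        if self.label not in (1, 2):
            raise ValidationError(f"class label must be 1 or 2, got {self.label}")


@dataclass
class EpochSet:
    """Ordered, homogeneous collection of labeled epochs."""

    epochs: list[Epoch]
    fs: float

    def __post_init__(self) -> None:
        if self.epochs:
            ch = self.epochs[0].data.shape[0]
            T = self.epochs[0].data.shape[1]
            for i, e in enumerate(self.epochs):
                if e.data.shape != (ch, T):
                    raise ValidationError(
                        f"epoch {i} has shape {e.data.shape}, expected {(ch, T)}"
                    )
                if e.fs != self.fs:
                    raise ValidationError(f"epoch {i} fs {e.fs} != set fs {self.fs}")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def n_channels(self) -> int:
        return self.epochs[0].data.shape[0] if self.epochs else 0

    @property
    def n_times(self) -> int:
        return self.epochs[0].data.shape[1] if self.epochs else 0

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.epochs], dtype=int)

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for e in self.epochs:
            counts[e.label] = counts.get(e.label, 0) + 1
        return counts

    def to_array(self) -> np.ndarray:
        """Stack epochs into an (n_epochs, n_channels, n_times) array."""
        return np.stack([e.data for e in self.epochs]) if self.epochs else np.empty((0, 0, 0))

    def subset(self, indices) -> "EpochSet":
        return EpochSet([self.epochs[i] for i in indices], self.fs)

    def select_channels(self, picks: list[int]) -> "EpochSet":
        return EpochSet(
            [Epoch(e.data[picks], e.label, e.fs) for e in self.epochs], self.fs
        )


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

_FORMATS = ("mat", "hdf5", "csv")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mat":
        return "mat"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer container format from suffix {suffix!r}")


def load_recording(
    path,
    format: str | None = None,
    *,
    signal_field: str = "signal",
    fs_field: str = "fs",
    markers_field: str = "markers",
) -> EEGRecording:
    """Load a continuous EEG recording from a MAT, HDF5 or CSV container.

    Field names are configurable to accommodate the varying layouts of
    competition MAT-files.  CSV containers store channels as columns and use
    a ``<stem>.markers.json`` sidecar holding ``fs``, ``markers`` and
    optionally ``channel_names``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")

    if fmt == "mat":
        return _load_mat(path, signal_field, fs_field, markers_field)
    if fmt == "hdf5":
        return _load_hdf5(path, signal_field, fs_field, markers_field)
    return _load_csv(path)


def _markers_from_array(arr: np.ndarray) -> list[tuple[int, int]]:
    arr = np.atleast_2d(np.asarray(arr))
    if arr.size == 0:
        return []
    if arr.shape[1] != 2 and arr.shape[0] == 2:
        arr = arr.T
    return [(int(r[0]), int(r[1])) for r in arr]


def _load_mat(path: Path, signal_field, fs_field, markers_field) -> EEGRecording:
    try:
        contents = scipy.io.loadmat(path, squeeze_me=False)
    except NotImplementedError:
        # v7.3 MAT-files are HDF5 underneath
        return _load_hdf5(path, signal_field, fs_field, markers_field)
    for name in (signal_field, fs_field, markers_field):
        if name not in contents:
            raise FormatError(f"MAT-file {path.name} is missing field {name!r}")
    signal = np.asarray(contents[signal_field], dtype=float)
    fs = float(np.asarray(contents[fs_field]).ravel()[0])
    markers = _markers_from_array(contents[markers_field])
    names = None
    if "channel_names" in contents:
        raw = np.asarray(contents["channel_names"]).ravel()
        names = [str(np.asarray(x).ravel()[0]) for x in raw]
    return EEGRecording(signal, fs, names or [], markers)


def _load_hdf5(path: Path, signal_field, fs_field, markers_field) -> EEGRecording:
    with h5py.File(path, "r") as f:
        for name in (signal_field, fs_field, markers_field):
            if name not in f:
                raise FormatError(f"HDF5 file {path.name} is missing field {name!r}")
        signal = np.asarray(f[signal_field], dtype=float)
        fs = float(np.asarray(f[fs_field]).ravel()[0])
        markers = _markers_from_array(np.asarray(f[markers_field]))
        names = []
        if "channel_names" in f:
            names = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in np.asarray(f["channel_names"]).ravel()
            ]
    return EEGRecording(signal, fs, names, markers)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".markers.json")


def _load_csv(path: Path) -> EEGRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"CSV container {path.name} needs sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for name in ("fs", "markers"):
        if name not in meta:
            raise FormatError(f"sidecar {sidecar.name} is missing field {name!r}")
    table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    signal = table.T  # channels as columns on disk
    markers = [(int(o), int(c)) for o, c in meta["markers"]]
    names = meta.get("channel_names", [])
    return EEGRecording(signal, float(meta["fs"]), names, markers)


def save_recording(rec: EEGRecording, path, format: str | None = None) -> Path:
    """Write a recording in any of the supported container layouts."""
    path = Path(path)
    fmt = format or _infer_format(path)
    markers = np.array(rec.markers, dtype=np.int64).reshape(-1, 2)
    if fmt == "mat":
        scipy.io.savemat(
            path,
            {
                "signal": rec.signal,
                "fs": rec.fs,
                "markers": markers,
                "channel_names": np.array(rec.channel_names, dtype=object),
            },
        )
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=rec.signal)
            f.create_dataset("fs", data=rec.fs)
            f.create_dataset("markers", data=markers)
            f.create_dataset(
                "channel_names",
                data=np.array([n.encode() for n in rec.channel_names]),
            )
    elif fmt == "csv":
        header = ",".join(rec.channel_names)
        np.savetxt(path, rec.signal.T, delimiter=",", header=header, comments="")
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "fs": rec.fs,
                    "markers": [[int(o), int(c)] for o, c in rec.markers],
                    "channel_names": rec.channel_names,
                }
            )
        )
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# segmentation and filtering
# ---------------------------------------------------------------------------


def segment_epochs(
    rec: EEGRecording, epoch_seconds: float = 3.0, offset_seconds: float = 0.0
) -> EpochSet:
    """Cut one fixed-length epoch per marker, anchored at the cue onset.

    The window is half-open ``[onset + offset, onset + offset + T)`` with
    ``T = round(epoch_seconds * fs)``.
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    T = int(round(epoch_seconds * rec.fs))
    off = int(round(offset_seconds * rec.fs))
    epochs = []
    for i, (onset, label) in enumerate(rec.markers):
        start = onset + off
        if start < 0 or start + T > rec.n_samples:
            raise ValidationError(
                f"marker {i} window [{start}, {start + T}) overruns "
                f"signal of {rec.n_samples} samples"
            )
        epochs.append(Epoch(rec.signal[:, start : start + T].copy(), label, rec.fs))
    return EpochSet(epochs, rec.fs)


def bandpass(
    es: EpochSet, low_hz: float = 8.0, high_hz: float = 15.0, order: int = 4
) -> EpochSet:
    """Zero-phase Butterworth band-pass applied channel-wise to every epoch.

    Forward-backward filtering (``sosfiltfilt``) keeps the phase of the
    oscillatory sources intact, which matters because the spatial-filter fit
    downstream works on epoch covariances.
    """
    nyq = es.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < {nyq} (Nyquist)"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=es.fs, output="sos")
    filtered = [
        Epoch(sosfiltfilt(sos, e.data, axis=1), e.label, e.fs) for e in es.epochs
    ]
    return EpochSet(filtered, es.fs)


def save_epochs(es: EpochSet, path) -> Path:
    """Serialize an epoch set to HDF5 (data cube, labels, fs)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.to_array())
        f.create_dataset("labels", data=es.labels)
        f.create_dataset("fs", data=es.fs)
    return path


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"])
        labels = np.asarray(f["labels"], dtype=int)
        fs = float(np.asarray(f["fs"]).ravel()[0])
    return EpochSet([Epoch(d, int(l), fs) for d, l in zip(data, labels)], fs)
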