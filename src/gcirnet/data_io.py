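"""Containers and I/O for multichannel EEG trials, montages and configs.

The pipeline operates on three plain containers:

``Recording``
    A single continuous or per-trial EEG signal, channels x samples, in
    microvolts, with its sampling rate and channel labels.
``TrialSet``
    A stack of equally shaped trials with one-hot class labels and
    free-form metadata (subject id, dataset tag, analysis window).
``Montage``
    Electrode labels with 3D positions normalized onto a unit sphere and
    their 2D azimuthal-equidistant projection used for image rendering.

Trials round-trip through an HDF5 container (datasets ``/trials`` and
``/labels``; scalar attributes for the sampling rate, channel labels and a
JSON-encoded metadata blob).  Montages are plain TSV tables with header
``label x y z``.  EDF recordings are imported (read-only) through MNE.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "Recording",
    "TrialSet",
    "Montage",
    "load_montage",
    "save_montage",
    "import_edf",
    "save_trials",
    "load_trials",
    "EEGMMIDB_CHANNELS",
    "DEFAULT_EEGMMIDB_LABEL_MAP",
]


@dataclass
class Recording:
    """A channels x samples EEG signal with sampling rate and labels."""

    signal: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        c, tau = self.signal.shape
        if c < 3:
            raise ValueError(f"need at least 3 channels, got {c}")
        if tau < 2:
            raise ValueError(f"need at least 2 samples, got {tau}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != c:
            raise ValueError("channel_labels length does not match signal rows")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class TrialSet:
    """Stack of trials (n x C x tau) with one-hot labels (n x Q)."""

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: list[str]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.trials.ndim != 3:
            raise ValueError("trials must be n x C x tau")
        if self.labels.ndim != 2 or self.labels.shape[0] != self.trials.shape[0]:
            raise ValueError("labels must be n x Q matching the trial count")
        if self.labels.shape[1] < 2:
            raise ValueError("need at least 2 classes")
        if not np.allclose(self.labels.sum(axis=1), 1.0):
            raise ValueError("each label row must be one-hot (sum to 1)")
        if len(self.channel_labels) != self.trials.shape[1]:
            raise ValueError("channel_labels length does not match trials")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_classes(self) -> int:
        return self.labels.shape[1]

    @property
    def class_indices(self) -> np.ndarray:
        """Integer class per trial (argmax over the one-hot rows)."""
        return np.argmax(self.labels, axis=1)

    def recording(self, i: int) -> Recording:
        """View trial *i* as a :class:`Recording`."""
        return Recording(self.trials[i], self.fs, list(self.channel_labels))

    def subset(self, idx: Sequence[int]) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(
            self.trials[idx],
            self.labels[idx],
            self.fs,
            list(self.channel_labels),
            dict(self.metadata),
        )


@dataclass
class Montage:
    """Electrode labels with unit-sphere 3D positions and 2D projection."""

    labels: list[str]
    xyz: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.xyz.shape != (len(self.labels), 3):
            raise ValueError("xyz must be C x 3")
        norms = np.linalg.norm(self.xyz, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("xyz rows must lie on the unit sphere")
        if self.xy.shape != (len(self.labels), 2) or not np.all(np.isfinite(self.xy)):
            raise ValueError("xy must be a finite C x 2 array")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def subset(self, labels: Sequence[str]) -> "Montage":
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"labels not in montage: {missing}")
        idx = [index[lab] for lab in labels]
        return Montage(list(labels), self.xyz[idx], self.xy[idx])


# 64-channel 10-10 montage used by both benchmark recordings (order of the
# PhysioNet motor imagery corpus, MNE capitalization).
EEGMMIDB_CHANNELS: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FT8", "T7", "T8", "T9", "T10", "TP7", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

# Annotation regrouping for the PhysioNet motor imagery corpus: original
# labels 0..9 collapse to five classes; 10 and 11 (non-motor) are dropped.
DEFAULT_EEGMMIDB_LABEL_MAP: dict[int, int | None] = {
    0: 0, 1: 0,          # right hand
    2: 1, 3: 1,          # left hand
    4: 2, 5: 2,          # both hands
    6: 3, 7: 3,          # both feet
    8: 4, 9: 4,          # rest
    10: None, 11: None,  # non-motor tasks, discarded
}


def _builtin_positions(labels: Sequence[str]) -> np.ndarray:
    """Unit-sphere 3D positions for 10-10 labels from the MNE standard set."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    lut = {k.lower(): np.asarray(v, dtype=np.float64) for k, v in pos.items()}
    out = np.empty((len(labels), 3))
    for i, lab in enumerate(labels):
        key = lab.lower()
        if key not in lut:
            raise KeyError(f"unknown 10-10 electrode label: {lab}")
        out[i] = lut[key]
    return out


def load_montage(path_or_name: str | Path) -> Montage:
    """Load a montage from a ``label x y z`` TSV table or a built-in name.

    ``"standard_10_10_64"`` yields the 64-channel 10-10 layout shared by
    the two benchmark recording systems.  3D positions are renormalized to
    unit length and projected to 2D with an azimuthal equidistant
    projection about the vertex.
    """
    from .topomap import project_montage

    if str(path_or_name) == "standard_10_10_64":
        labels = list(EEGMMIDB_CHANNELS)
        xyz = _builtin_positions(labels)
    else:
        path = Path(path_or_name)
        rows: list[tuple[str, float, float, float]] = []
        with open(path) as fh:
            header = fh.readline().split()
            if [h.lower() for h in header[:4]] != ["label", "x", "y", "z"]:
                raise ValueError("montage table must have header 'label x y z'")
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                rows.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
        labels = [r[0] for r in rows]
        xyz = np.array([r[1:] for r in rows], dtype=np.float64)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate electrode labels in montage")
    if len(labels) < 3:
        raise ValueError("montage needs at least 3 electrodes")
    norms = np.linalg.norm(xyz, axis=1)
    if np.any(norms == 0):
        raise ValueError("electrode at the sphere origin")
    xyz = xyz / norms[:, None]
    xy = project_montage(xyz)
    return Montage(labels, xyz, xy)


def save_montage(m: Montage, path: str | Path) -> None:
    """Write a montage as a ``label x y z`` TSV table."""
    with open(path, "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for lab, (x, y, z) in zip(m.labels, m.xyz):
            fh.write(f"{lab}\t{x:.10f}\t{y:.10f}\t{z:.10f}\n")


def save_trials(ts: TrialSet, path: str | Path) -> None:
    """Write a TrialSet to an HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=ts.trials)
        f.create_dataset("labels", data=ts.labels)
        f.attrs["fs"] = float(ts.fs)
        f.attrs["channel_labels"] = json.dumps(list(ts.channel_labels))
        f.attrs["metadata"] = json.dumps(ts.metadata)


def load_trials(path: str | Path) -> TrialSet:
    """Read a TrialSet written by :func:`save_trials`."""
    with h5py.File(path, "r") as f:
        for name in ("trials", "labels"):
            if name not in f:
                raise KeyError(f"container missing dataset '{name}'")
        for attr in ("fs", "channel_labels", "metadata"):
            if attr not in f.attrs:
                raise KeyError(f"container missing attribute '{attr}'")
        trials = f["trials"][()]
        labels = f["labels"][()]
        fs = float(f.attrs["fs"])
        channel_labels = json.loads(f.attrs["channel_labels"])
        metadata = json.loads(f.attrs["metadata"])
    return TrialSet(trials, labels, fs, channel_labels, metadata)


def import_edf(
    path: str | Path,
    label_map: Mapping[int, int | None] | None = None,
    window: float = 4.1,
    event_id: Mapping[str, int] | None = None,
) -> TrialSet:
    """Cut an annotated EDF recording into a TrialSet.

    Trials start at each annotation onset and span ``window`` seconds
    (half-open sample window, start index ``round(t * fs)``).  Annotation
    codes are regrouped through ``label_map`` (code -> class index, or
    ``None`` to discard); the default is the PhysioNet motor-imagery
    regrouping.  Trials whose window runs past the end of the record are
    dropped with a warning.  All trials from one file share the file's
    sampling rate, so they have a common length; harmonizing lengths
    across files recorded at different rates is the caller's job
    (resample via :func:`gcirnet.preprocess.standardize`, or crop to the
    shortest trial).
    """
    import mne

    if label_map is None:
        label_map = DEFAULT_EEGMMIDB_LABEL_MAP
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # MNE loads volts; container stores microvolts
    if raw.annotations is None or len(raw.annotations) == 0:
        raise ValueError("EDF file has no annotations to segment on")
    events, found_ids = mne.events_from_annotations(raw, event_id=event_id, verbose="error")
    n_samp = int(round(window * fs))
    classes = sorted({v for v in label_map.values() if v is not None})
    class_pos = {c: i for i, c in enumerate(classes)}
    q = len(classes)
    trials, labels = [], []
    dropped = 0
    for onset, _, code in events:
        mapped = label_map.get(int(code))
        if mapped is None:
            continue
        start = int(onset)
        stop = start + n_samp
        if stop > data.shape[1]:
            dropped += 1
            continue
        trials.append(data[:, start:stop])
        onehot = np.zeros(q)
        onehot[class_pos[mapped]] = 1.0
        labels.append(onehot)
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) whose window exceeded the record end")
    if not trials:
        raise ValueError("no trials survived annotation mapping")
    meta = {
        "source": str(path),
        "window_s": window,
        "dropped_trials": dropped,
        "annotation_ids": {str(k): int(v) for k, v in found_ids.items()},
    }
    return TrialSet(np.stack(trials), np.stack(labels), fs, list(raw.ch_names), meta)
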