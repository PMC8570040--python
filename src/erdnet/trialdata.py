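"""Labeled EEG trial sets: container, HDF5 archive I/O, windowing, channel selection.

The canonical unit of data is a trial set: ``n`` segmented trials recorded on
``E`` electrodes over ``T`` samples, each trial carrying one of ``M``
motor-imagery class labels.  Signals are stored in microvolts; the simulator
emits the same unit so synthetic and recorded data flow through identical code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import h5py

__all__ = [
    "EEGTrialSet",
    "FormatError",
    "load_trialset",
    "save_trialset",
    "crop_cue_window",
    "select_channels",
    "load_gdf_trialset",
]


class FormatError(ValueError):
    """An archive is missing a required array or attribute."""


@dataclass
class EEGTrialSet:
    """A set of labeled EEG trials.

    Parameters
    ----------
    signals : ndarray, shape (n, E, T)
        Trial tensor in microvolts.  Coerced to float32 (the archive dtype)
        so that a save/load round trip is exact.
    labels : ndarray, shape (n,)
        Integer class labels in ``[0, M)``.
    sampling_rate : float
        Sampling rate in Hz, strictly positive.
    channel_names : list of str, length E
    class_names : list of str, length M
    """

    signals: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signals.ndim != 3:
            raise ValueError(
                f"signals must be (trials, electrodes, samples); got shape {self.signals.shape}"
            )
        if self.labels.ndim != 1 or self.labels.shape[0] != self.signals.shape[0]:
            raise ValueError(
                f"labels length {self.labels.shape} does not match {self.signals.shape[0]} trials"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.signals.shape[1])]
        if not self.class_names:
            m = int(self.labels.max()) + 1 if self.labels.size else 1
            self.class_names = [f"class{i}" for i in range(m)]
        self.channel_names = [str(c) for c in self.channel_names]
        self.class_names = [str(c) for c in self.class_names]
        if len(self.channel_names) != self.signals.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.signals.shape[1]} electrodes"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError(
                f"labels must lie in [0, {self.n_classes}); got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")

    # -- shape accessors (n, E, T, M in the field's notation) --
    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEGTrialSet):
            return NotImplemented
        return (
            np.array_equal(self.signals, other.signals)
            and np.array_equal(self.labels, other.labels)
            and float(self.sampling_rate) == float(other.sampling_rate)
            and self.channel_names == other.channel_names
            and self.class_names == other.class_names
        )


def save_trialset(trialset: EEGTrialSet, path) -> None:
    """Write a trial set to an HDF5 archive.

    Layout: datasets ``signals`` (float32) and ``labels`` (int16), root
    attributes ``sampling_rate``, ``channel_names``, ``class_names``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=trialset.signals.astype(np.float32))
        f.create_dataset("labels", data=trialset.labels.astype(np.int16))
        f.attrs["sampling_rate"] = float(trialset.sampling_rate)
        f.attrs["channel_names"] = [str(c) for c in trialset.channel_names]
        f.attrs["class_names"] = [str(c) for c in trialset.class_names]


def load_trialset(path) -> EEGTrialSet:
    """Read a trial set archive written by :func:`save_trialset`.

    Raises
    ------
    FormatError
        If a required dataset or attribute is absent.
    ValueError
        If the stored arrays violate the trial-set invariants
        (e.g. a label outside ``[0, M)``).
    """
    with h5py.File(path, "r") as f:
        for key in ("signals", "labels"):
            if key not in f:
                raise FormatError(f"archive {path!s} is missing dataset '{key}'")
        for key in ("sampling_rate", "channel_names", "class_names"):
            if key not in f.attrs:
                raise FormatError(f"archive {path!s} is missing attribute '{key}'")
        return EEGTrialSet(
            signals=f["signals"][()],
            labels=f["labels"][()].astype(np.int64),
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            class_names=[str(c) for c in f.attrs["class_names"]],
        )


def crop_cue_window(
    continuous: np.ndarray,
    cue_onset: int,
    duration_s: float,
    sampling_rate: float,
) -> np.ndarray:
    """Extract the cue-aligned imagery window from continuous trial epochs.

    Convention: 0-based sample indices, half-open window
    ``[cue_onset, cue_onset + round(duration_s * sampling_rate))``.
    The competition protocol keeps the 4 s from cue onset to the end of the
    imagery period, i.e. 1000 samples at 250 Hz.
    """
    continuous = np.asarray(continuous)
    n_keep = int(round(duration_s * sampling_rate))
    if cue_onset < 0:
        raise IndexError(f"cue_onset must be non-negative, got {cue_onset}")
    if cue_onset + n_keep > continuous.shape[-1]:
        raise IndexError(
            f"window [{cue_onset}, {cue_onset + n_keep}) exceeds the "
            f"{continuous.shape[-1]}-sample recording"
        )
    return continuous[..., cue_onset : cue_onset + n_keep]


def select_channels(trialset: EEGTrialSet, keep: list[str]) -> EEGTrialSet:
    """Restrict a trial set to the named channels, in the order given."""
    index = {name: i for i, name in enumerate(trialset.channel_names)}
    missing = [name for name in keep if name not in index]
    if missing:
        raise KeyError(f"unknown channel name(s): {missing}")
    idx = [index[name] for name in keep]
    return replace(
        trialset,
        signals=trialset.signals[:, idx, :],
        channel_names=[trialset.channel_names[i] for i in idx],
    )


# Cue-event annotation codes used by the BCI competition IV GDF files.
_GDF_CLASS_EVENTS = {
    "2a": {"769": 0, "770": 1, "771": 2, "772": 3},
    "2b": {"769": 0, "770": 1},
}
_GDF_CLASS_NAMES = {
    "2a": ["left_hand", "right_hand", "feet", "tongue"],
    "2b": ["left_hand", "right_hand"],
}


def load_gdf_trialset(
    path,
    dataset: str = "2a",
    duration_s: float = 4.0,
    eeg_channels: list[str] | None = None,
) -> EEGTrialSet:
    """Epoch a BCI competition IV-2a/2b GDF recording into a trial set.

    Optional reader for locally downloaded competition files; requires mne.
    The trial count is whatever the event table yields.  EOG channels are
    dropped unless an explicit channel list is given.
    """
    import mne  # local import: optional dependency

    if dataset not in _GDF_CLASS_EVENTS:
        raise ValueError(f"dataset must be '2a' or '2b', got {dataset!r}")
    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    code_map = {
        event_id[code]: cls
        for code, cls in _GDF_CLASS_EVENTS[dataset].items()
        if code in event_id
    }
    data = raw.get_data(units="uV")
    names = list(raw.ch_names)
    n_keep = int(round(duration_s * sfreq))
    trials, labels = [], []
    for onset, _, code in events:
        if code not in code_map or onset + n_keep > data.shape[1]:
            continue
        trials.append(data[:, onset : onset + n_keep])
        labels.append(code_map[code])
    if not trials:
        raise ValueError(f"no cue events found in {path!s}")
    ts = EEGTrialSet(
        signals=np.stack(trials),
        labels=np.asarray(labels),
        sampling_rate=sfreq,
        channel_names=names,
        class_names=_GDF_CLASS_NAMES[dataset],
    )
    if eeg_channels is None:
        eeg_channels = [c for c in names if "EOG" not in c.upper()]
    return select_channels(ts, eeg_channels)
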