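"""Epoched EEG trial container and HDF5 interchange format.

A :class:`TrialSet` holds a dense block of epoched motor-imagery trials in
the canonical time-major orientation ``(n_trials, T, C)`` — ``T`` timestamps
by ``C`` electrodes, in microvolts — together with integer class labels.
Every input-layout transform in :mod:`eegshapes.shapes` starts from this
single canonical orientation.

Trial sets round-trip bit-exactly through a small HDF5 "trial archive"
(datasets ``/X`` float32 and ``/y`` int32, plus root attributes), so
simulated and imported data share one on-disk format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "TrialSet",
    "DatasetSpec",
    "TrialSetError",
    "ArchiveFormatError",
    "save_trial_archive",
    "load_trial_archive",
    "select_classes",
    "dataset_descriptor",
    "DATASET_SPECS",
]


class TrialSetError(ValueError):
    """A TrialSet invariant is violated."""


class ArchiveFormatError(IOError):
    """A trial archive does not match the expected HDF5 layout."""


def default_channel_names(n_channels: int) -> tuple[str, ...]:
    return tuple(f"ch{i + 1:02d}" for i in range(n_channels))


@dataclass(frozen=True)
class TrialSet:
    """Labelled epoched EEG trials in canonical (T, C) orientation.

    Parameters
    ----------
    trials
        Array of shape ``(n_trials, T, C)``, microvolts. Stored as float32.
    labels
        Integer array of length ``n_trials``; values index ``class_names``.
    class_names
        Ordered class labels, e.g. ``("left", "right")``.
    sampling_rate_hz
        Sampling rate of the epoched signal, > 0.
    subject_id
        Identifier of the recorded subject.
    channel_names
        Ordered electrode names of length ``C``.
    """

    trials: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    sampling_rate_hz: float
    subject_id: str = "S0"
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        trials = np.asarray(self.trials, dtype=np.float32)
        labels = np.asarray(self.labels, dtype=np.int32)
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        names = self.channel_names
        if not names:
            names = default_channel_names(trials.shape[2] if trials.ndim == 3 else 0)
        object.__setattr__(self, "channel_names", tuple(names))
        self._validate()

    def _validate(self) -> None:
        if self.trials.ndim != 3:
            raise TrialSetError(
                f"trials must be 3-axis (n_trials, T, C); got ndim={self.trials.ndim}"
            )
        n, t, c = self.trials.shape
        if t < 1 or c < 1:
            raise TrialSetError(f"T and C must be >= 1; got T={t}, C={c}")
        if self.labels.ndim != 1 or len(self.labels) != n:
            raise TrialSetError(
                f"labels length {self.labels.shape} does not match n_trials={n}"
            )
        if not self.class_names:
            raise TrialSetError("class_names must be non-empty")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise TrialSetError(
                f"labels must lie in [0, {len(self.class_names)}); "
                f"got range [{self.labels.min()}, {self.labels.max()}]"
            )
        if not self.sampling_rate_hz > 0:
            raise TrialSetError(f"sampling_rate_hz must be > 0; got {self.sampling_rate_hz}")
        if len(self.channel_names) != c:
            raise TrialSetError(
                f"channel_names length {len(self.channel_names)} != C={c}"
            )

    # -- convenience geometry accessors -------------------------------------

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_timestamps(self) -> int:
        return self.trials.shape[1]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        """Number of trials per class, ordered like ``class_names``."""
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices: np.ndarray) -> "TrialSet":
        """A new TrialSet containing the given trial indices, in order."""
        idx = np.asarray(indices)
        return replace(self, trials=self.trials[idx], labels=self.labels[idx])

    def equals(self, other: "TrialSet") -> bool:
        return (
            self.trials.shape == other.trials.shape
            and np.array_equal(self.trials, other.trials)
            and np.array_equal(self.labels, other.labels)
            and self.class_names == other.class_names
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.subject_id == other.subject_id
            and self.channel_names == other.channel_names
        )


@dataclass(frozen=True)
class DatasetSpec:
    """Geometry descriptor of a benchmark motor-imagery dataset."""

    name: str
    n_subjects: int
    n_channels: int
    sampling_rate_hz: float
    class_names: tuple[str, ...]
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.channel_names:
            object.__setattr__(
                self, "channel_names", default_channel_names(self.n_channels)
            )


# 10-20 montage of the 22-electrode Graz 2a cap and the 3 bipolar 2b channels.
_MONTAGE_2A = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
)
_MONTAGE_2B = ("C3", "Cz", "C4")

DATASET_SPECS: dict[str, DatasetSpec] = {
    "BCI-IV-2A": DatasetSpec(
        name="BCI-IV-2A",
        n_subjects=9,
        n_channels=22,
        sampling_rate_hz=250.0,
        class_names=("left", "right", "feet", "tongue"),
        channel_names=_MONTAGE_2A,
    ),
    "BCI-IV-2B": DatasetSpec(
        name="BCI-IV-2B",
        n_subjects=9,
        n_channels=3,
        sampling_rate_hz=250.0,
        class_names=("left", "right"),
        channel_names=_MONTAGE_2B,
    ),
}


def dataset_descriptor(name: str) -> DatasetSpec:
    """Return the constant geometry descriptor for a supported benchmark.

    ``"BCI-IV-2A"``: 9 subjects, 22 channels, 250 Hz, classes
    (left, right, feet, tongue). ``"BCI-IV-2B"``: 9 subjects, 3 bipolar
    channels, 250 Hz, classes (left, right).
    """
    try:
        return DATASET_SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown dataset {name!r}; supported: {sorted(DATASET_SPECS)}"
        ) from None


def save_trial_archive(ts: TrialSet, path: str | os.PathLike) -> None:
    """Write a TrialSet to an HDF5 trial archive.

    Layout: datasets ``/X`` (float32, n_trials x T x C) and ``/y`` (int32),
    root attributes ``sampling_rate_hz``, ``subject_id``, ``class_names``,
    ``channel_names``. The float32 payload round-trips bit-exactly.
    """
    ts._validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ts.trials.astype(np.float32))
        f.create_dataset("y", data=ts.labels.astype(np.int32))
        f.attrs["sampling_rate_hz"] = float(ts.sampling_rate_hz)
        f.attrs["subject_id"] = ts.subject_id
        f.attrs["class_names"] = list(ts.class_names)
        f.attrs["channel_names"] = list(ts.channel_names)


_REQUIRED_ATTRS = ("sampling_rate_hz", "subject_id", "class_names", "channel_names")


def load_trial_archive(path: str | os.PathLike) -> TrialSet:
    """Load a trial archive written by :func:`save_trial_archive`.

    Missing datasets or attributes raise :class:`ArchiveFormatError`; label
    or shape inconsistencies raise :class:`TrialSetError`. Nothing is ever
    silently defaulted.
    """
    with h5py.File(path, "r") as f:
        for key in ("X", "y"):
            if key not in f:
                raise ArchiveFormatError(f"archive {path} is missing dataset /{key}")
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise ArchiveFormatError(
                    f"archive {path} is missing root attribute {attr!r}"
                )
        X = np.asarray(f["X"], dtype=np.float32)
        y = np.asarray(f["y"], dtype=np.int32)
        class_names = tuple(str(s) for s in f.attrs["class_names"])
        channel_names = tuple(str(s) for s in f.attrs["channel_names"])
        return TrialSet(
            trials=X,
            labels=y,
            class_names=class_names,
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            subject_id=str(f.attrs["subject_id"]),
            channel_names=channel_names,
        )


def select_classes(ts: TrialSet, keep: tuple[str, ...] | list[str]) -> TrialSet:
    """Restrict a TrialSet to the named classes, re-indexing labels densely.

    Labels are re-indexed over ``keep`` in the given order; trial order is
    otherwise preserved. Used e.g. to reduce a four-class left/right/feet/
    tongue set to the left/right pair.
    """
    keep = tuple(keep)
    unknown = [k for k in keep if k not in ts.class_names]
    if unknown:
        raise KeyError(f"unknown class names {unknown}; available: {ts.class_names}")
    if not keep:
        raise ValueError("keep must name at least one class")
    old_idx = {name: i for i, name in enumerate(ts.class_names)}
    remap = {old_idx[name]: j for j, name in enumerate(keep)}
    mask = np.isin(ts.labels, list(remap))
    if not mask.any():
        raise ValueError(f"no trials belong to classes {keep}")
    new_labels = np.array([remap[int(l)] for l in ts.labels[mask]], dtype=np.int32)
    return TrialSet(
        trials=ts.trials[mask],
        labels=new_labels,
        class_names=keep,
        sampling_rate_hz=ts.sampling_rate_hz,
        subject_id=ts.subject_id,
        channel_names=ts.channel_names,
    )
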