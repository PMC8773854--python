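"""Labeled multichannel EEG epochs and their on-disk HDF5 archive.

The central container is :class:`EpochSet`: a ``(n_trials, n_channels,
n_samples)`` array of epoched EEG with integer class labels, a sampling
rate and channel/class name metadata.  Motor-imagery trials from BCI
Competition IV-2a, for instance, arrive as ``(288, 22, 1125)`` per session
(22 electrodes, 4.5 s at 250 Hz).

The canonical storage format is a single self-describing HDF5 file with
``data`` (float32) and ``labels`` (int) datasets; metadata lives in root
attributes.  Roundtrips are bit-exact for float32 data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["EpochSet", "write_epoch_archive", "read_epoch_archive"]


@dataclass
class EpochSet:
    """Epoched multichannel EEG trials with labels and metadata.

    Parameters
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` float array, raw amplitude
        (µV) or standardized units.
    labels
        ``(n_trials,)`` integer class labels in ``[0, n_classes)``.
    fs
        Sampling rate in Hz.
    channel_names
        One name per channel.
    class_names
        One name per class; labels index into this list.
    subject_id
        Optional subject identifier (e.g. ``"A01"``).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])] if self.data.ndim == 3 else []
        if not self.class_names and self.labels.size:
            self.class_names = [f"class{i}" for i in range(int(self.labels.max()) + 1)]
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated field."""
        if self.data.ndim != 3:
            raise ValidationError(f"data: expected 3-D (trials, channels, samples), got ndim={self.data.ndim}")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.data.shape[0]:
            raise ValidationError(
                f"labels: length {self.labels.shape[0] if self.labels.ndim == 1 else self.labels.shape} "
                f"does not match {self.data.shape[0]} trials"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError(f"labels: expected integer dtype, got {self.labels.dtype}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError(
                f"channel_names: {len(self.channel_names)} names for {self.data.shape[1]} channels"
            )
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValidationError(
                f"labels: values must lie in [0, {len(self.class_names)}), "
                f"got range [{self.labels.min()}, {self.labels.max()}]"
            )
        if not self.fs > 0:
            raise ValidationError(f"fs: sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data: contains non-finite values")

    # -- conveniences --------------------------------------------------
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
    def n_classes(self) -> int:
        return len(self.class_names)

    def with_data(self, data: np.ndarray) -> "EpochSet":
        """Copy of this set with ``data`` replaced (metadata preserved)."""
        return replace(self, data=data)

    def subset(self, idx: np.ndarray) -> "EpochSet":
        """Trials selected by integer or boolean index."""
        return replace(self, data=self.data[idx], labels=self.labels[idx])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EpochSet(n_trials={self.n_trials}, n_channels={self.n_channels}, "
            f"n_samples={self.n_samples}, fs={self.fs}, n_classes={self.n_classes}, "
            f"subject_id={self.subject_id!r})"
        )


def write_epoch_archive(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to a single HDF5 archive.

    Layout: datasets ``data`` (float32) and ``labels`` (int64); root
    attributes ``fs``, ``channel_names``, ``class_names`` and, when set,
    ``subject_id``.  Data is stored as float32, so float32 inputs
    roundtrip bit-exactly.
    """
    epochs.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32, copy=False))
        f.create_dataset("labels", data=epochs.labels.astype(np.int64, copy=False))
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        f.attrs["class_names"] = [str(c) for c in epochs.class_names]
        if epochs.subject_id is not None:
            f.attrs["subject_id"] = str(epochs.subject_id)


def read_epoch_archive(path: str | Path) -> EpochSet:
    """Read an HDF5 epoch archive written by :func:`write_epoch_archive`.

    Raises
    ------
    FormatError
        If a required dataset or attribute is missing.
    ValidationError
        If the stored content violates an :class:`EpochSet` invariant.
    """
    with h5py.File(path, "r") as f:
        for name in ("data", "labels"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset '{name}'")
        for attr in ("fs", "channel_names", "class_names"):
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute '{attr}'")
        data = f["data"][...]
        labels = f["labels"][...]
        fs = float(f.attrs["fs"])
        channel_names = [str(c) for c in f.attrs["channel_names"]]
        class_names = [str(c) for c in f.attrs["class_names"]]
        subject_id = str(f.attrs["subject_id"]) if "subject_id" in f.attrs else None
    return EpochSet(
        data=data,
        labels=labels,
        fs=fs,
        channel_names=channel_names,
        class_names=class_names,
        subject_id=subject_id,
    )
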