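"""Continuous recordings to standardized fixed-length epochs.

The pipeline mirrors the minimal preparation used for within-subject
motor-imagery decoding:

* window extraction — each trial is the 4.5 s segment starting 0.5 s
  before the cue (1125 samples at 250 Hz);
* per-channel standardization — statistics fitted on the training
  session only, applied to both sessions;
* optional polyphase resampling (e.g. 500 Hz recordings to 250 Hz) and
  channel subselection (e.g. 128-channel montages reduced to 44).

No band-pass filtering or artifact correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.signal import resample_poly

from .epochs import EpochSet
from .errors import EpochWindowError, ValidationError

__all__ = [
    "WindowSpec",
    "StandardizationStats",
    "extract_epochs",
    "fit_standardization",
    "apply_standardization",
    "resample_epochs",
    "select_channels",
]

logger = logging.getLogger(__name__)

#: standard deviations below this are treated as degenerate (flat channel)
DEGENERATE_STD = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """Epoch window relative to the cue.

    ``pre_cue_s`` seconds before the cue to ``pre_cue_s + total_s`` after
    its start; defaults give the 4.5 s window ``[cue - 0.5 s, cue + 4 s]``.
    """

    pre_cue_s: float = 0.5
    total_s: float = 4.5

    def __post_init__(self) -> None:
        if not self.total_s > 0:
            raise ValidationError(f"total_s must be positive, got {self.total_s}")
        if self.pre_cue_s < 0:
            raise ValidationError(f"pre_cue_s must be non-negative, got {self.pre_cue_s}")
        if not self.pre_cue_s < self.total_s:
            raise ValidationError("pre_cue_s must be smaller than total_s")

    def n_samples(self, fs: float) -> int:
        return int(round(fs * self.total_s))


@dataclass
class StandardizationStats:
    """Per-channel mean/std fitted on training epochs.

    ``degenerate`` flags channels with std below :data:`DEGENERATE_STD`;
    those channels are mapped to all zeros when the stats are applied.
    """

    mean: np.ndarray
    std: np.ndarray
    degenerate: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]


def extract_epochs(
    recording: np.ndarray,
    fs: float,
    cue_times: Sequence[float],
    labels: Sequence[int],
    window: WindowSpec = WindowSpec(),
    channel_names: Sequence[str] | None = None,
    class_names: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> EpochSet:
    """Cut fixed-length epochs out of a continuous recording.

    Epoch ``k`` starts at sample ``round(fs * (cue_k - pre_cue_s))`` and
    has exactly ``round(fs * total_s)`` samples (half-open window).

    Raises
    ------
    EpochWindowError
        Naming the trial index, if any window leaves the recording.
    """
    recording = np.asarray(recording)
    if recording.ndim != 2:
        raise ValidationError(f"recording: expected (channels, samples), got ndim={recording.ndim}")
    if len(cue_times) != len(labels):
        raise ValidationError("cue_times and labels must have equal length")
    n = window.n_samples(fs)
    n_total = recording.shape[1]
    trials = np.empty((len(cue_times), recording.shape[0], n), dtype=recording.dtype)
    for k, cue in enumerate(cue_times):
        start = int(round(fs * (float(cue) - window.pre_cue_s)))
        if start < 0 or start + n > n_total:
            raise EpochWindowError(
                f"trial {k}: window [{start}, {start + n}) outside recording of {n_total} samples"
            )
        trials[k] = recording[:, start : start + n]
    return EpochSet(
        data=trials,
        labels=np.asarray(labels, dtype=np.int64),
        fs=fs,
        channel_names=list(channel_names) if channel_names is not None else [],
        class_names=list(class_names) if class_names is not None else [],
        subject_id=subject_id,
    )


def fit_standardization(train: EpochSet) -> StandardizationStats:
    """Per-channel mean/std over all training trials and samples."""
    if train.n_trials == 0:
        raise ValidationError("cannot fit standardization on an empty EpochSet")
    x = train.data.astype(np.float64, copy=False)
    mean = x.mean(axis=(0, 2))
    std = x.std(axis=(0, 2))
    degenerate = std < DEGENERATE_STD
    if degenerate.any():
        logger.warning(
            "degenerate channels (std < %g): %s", DEGENERATE_STD, np.flatnonzero(degenerate).tolist()
        )
    return StandardizationStats(mean=mean, std=std, degenerate=degenerate)


def apply_standardization(epochs: EpochSet, stats: StandardizationStats) -> EpochSet:
    """``x -> (x - mean_c) / std_c`` per channel; degenerate channels -> 0."""
    if epochs.n_channels != stats.n_channels:
        raise ValidationError(
            f"channel mismatch: epochs have {epochs.n_channels}, stats have {stats.n_channels}"
        )
    safe_std = np.where(stats.degenerate, 1.0, stats.std)
    out = (epochs.data - stats.mean[None, :, None]) / safe_std[None, :, None]
    if stats.degenerate.any():
        out[:, stats.degenerate, :] = 0.0
    return epochs.with_data(out.astype(np.float32))


def resample_epochs(epochs: EpochSet, target_fs: float, max_denominator: int = 1000) -> EpochSet:
    """Polyphase (anti-aliased) resampling along the time axis.

    ``2250`` samples at 500 Hz become ``1125`` at 250 Hz.  Both up- and
    down-sampling are allowed; a pure tone below the new Nyquist keeps its
    energy within 1%.
    """
    if not target_fs > 0:
        raise ValidationError(f"target_fs must be positive, got {target_fs}")
    if target_fs == epochs.fs:
        return replace(epochs)
    ratio = Fraction(target_fs / epochs.fs).limit_denominator(max_denominator)
    up, down = ratio.numerator, ratio.denominator
    out = resample_poly(epochs.data.astype(np.float64, copy=False), up, down, axis=2)
    return replace(epochs, data=out.astype(epochs.data.dtype), fs=float(target_fs))


def select_channels(epochs: EpochSet, keep: Sequence[str]) -> EpochSet:
    """Subselect and reorder channels by name (output order follows ``keep``)."""
    index = {name: i for i, name in enumerate(epochs.channel_names)}
    missing = [name for name in keep if name not in index]
    if missing:
        raise ValidationError(f"unknown channel names: {missing}")
    idx = [index[name] for name in keep]
    return replace(epochs, data=epochs.data[:, idx, :], channel_names=[str(n) for n in keep])
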