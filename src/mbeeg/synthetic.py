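"""Synthetic motor-imagery-like EEG epochs with controllable separability.

Each trial is pink (``1/f^alpha``) background noise on every channel plus
class-specific band-limited oscillations (mu ~10 Hz and beta ~20 Hz
analogues) confined to class-specific channel subsets — a stationary
idealization of the lateralized sensorimotor rhythm modulation that
motor-imagery decoders exploit.  The default regime matches the 4-class,
22-channel, 250 Hz setting of BCI Competition IV-2a epochs (1125 samples).

``snr`` is the amplitude ratio between the class oscillation and the
unit-RMS background on the signature channels; ``snr -> 0`` removes all
class information.

A nearest-centroid classifier on log band-power features is included as a
non-neural reference: it certifies that generated data is separable (and
how separable) independently of any network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import welch

from .epochs import EpochSet
from .errors import ValidationError

__all__ = ["ClassSignature", "SynthSpec", "generate", "bandpower_features", "bandpower_reference_classifier"]


@dataclass(frozen=True)
class ClassSignature:
    """Oscillatory fingerprint of one class.

    ``components`` is a list of ``(channel_index, frequency_Hz,
    relative_amplitude)`` triples; the composite oscillation on each
    signature channel is rescaled so its RMS equals ``snr`` times the
    background RMS.
    """

    name: str
    components: tuple[tuple[int, float, float], ...]


def _default_signatures() -> tuple[ClassSignature, ...]:
    # Lateralized mu/beta analogues on disjoint channel groups of a
    # 22-channel motor-cortex-style montage (7~C3, 9~Cz, 11~C4):
    # left hand -> contralateral right group, right hand -> left group,
    # feet -> midline mu variant, tongue -> inferior beta-dominant group.
    def group(channels, pairs):
        return tuple((ch, f, a) for ch in channels for f, a in pairs)

    return (
        ClassSignature("left_hand", group((10, 11, 12), ((10.0, 1.0), (22.0, 0.4)))),
        ClassSignature("right_hand", group((6, 7, 8), ((10.0, 1.0), (22.0, 0.4)))),
        ClassSignature("feet", group((3, 9, 15), ((12.0, 1.0),))),
        ClassSignature("tongue", group((17, 19, 21), ((20.0, 1.0), (9.0, 0.3)))),
    )


@dataclass
class SynthSpec:
    """Generator configuration; defaults emulate a IV-2a-like session."""

    n_trials_per_class: int = 10
    n_channels: int = 22
    fs: float = 250.0
    duration_s: float = 4.5
    class_signatures: tuple[ClassSignature, ...] = field(default_factory=_default_signatures)
    noise_exponent: float = 1.0
    snr: float = 2.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @property
    def n_classes(self) -> int:
        return len(self.class_signatures)

    def validate(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValidationError("n_trials_per_class must be >= 1")
        if self.n_channels < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("n_channels, fs and duration_s must be positive")
        if not self.snr >= 0:
            raise ValidationError(f"snr must be non-negative, got {self.snr}")
        for sig in self.class_signatures:
            for ch, f, a in sig.components:
                if not 0 <= ch < self.n_channels:
                    raise ValidationError(f"{sig.name}: channel index {ch} out of range")
                if not 0 < f < self.fs / 2:
                    raise ValidationError(f"{sig.name}: frequency {f} Hz not below Nyquist")
                if a <= 0:
                    raise ValidationError(f"{sig.name}: amplitude must be positive")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int, alpha: float) -> np.ndarray:
    """Spectrally shaped white noise with power ~ 1/f^alpha, unit RMS."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    scale[0] = 0.0  # no DC drift
    noise = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = noise.std(axis=-1, keepdims=True)
    return noise / np.where(rms > 0, rms, 1.0)


def generate(spec: SynthSpec) -> EpochSet:
    """Balanced labeled epochs, fully determined by ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_cls, n_per, n_ch, n_s = spec.n_classes, spec.n_trials_per_class, spec.n_channels, spec.n_samples
    t = np.arange(n_s) / spec.fs

    data = _pink_noise(rng, (n_cls * n_per, n_ch), n_s, spec.noise_exponent).astype(np.float64)
    labels = np.repeat(np.arange(n_cls), n_per)

    for c, sig in enumerate(spec.class_signatures):
        idx = np.flatnonzero(labels == c)
        # group components by channel so per-channel RMS can be normalized
        per_channel: dict[int, list[tuple[float, float]]] = {}
        for ch, f, a in sig.components:
            per_channel.setdefault(ch, []).append((f, a))
        for ch, comps in per_channel.items():
            phases = rng.uniform(0, 2 * np.pi, size=(len(idx), len(comps)))
            osc = np.zeros((len(idx), n_s))
            for j, (f, a) in enumerate(comps):
                osc += a * np.sin(2 * np.pi * f * t[None, :] + phases[:, j : j + 1])
            rms = osc.std(axis=-1, keepdims=True)
            osc = osc / np.where(rms > 0, rms, 1.0) * spec.snr
            data[idx, ch, :] += osc

    # shuffle trial order so classes are interleaved
    perm = rng.permutation(n_cls * n_per)
    return EpochSet(
        data=data[perm].astype(np.float32),
        labels=labels[perm].astype(np.int64),
        fs=spec.fs,
        channel_names=[f"ch{i}" for i in range(n_ch)],
        class_names=[sig.name for sig in spec.class_signatures],
        subject_id="synthetic",
    )


DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((8.0, 13.0), (13.0, 30.0))


def bandpower_features(
    epochs: EpochSet,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    channels: Sequence[int] | None = None,
) -> np.ndarray:
    """Log band-power per (channel, band), ``(n_trials, n_ch * n_bands)``."""
    for lo, hi in bands:
        if not 0 <= lo < hi <= epochs.fs / 2:
            raise ValidationError(f"band ({lo}, {hi}) Hz must lie below Nyquist ({epochs.fs / 2} Hz)")
    x = epochs.data if channels is None else epochs.data[:, list(channels), :]
    nperseg = min(x.shape[-1], 256)
    freqs, psd = welch(x, fs=epochs.fs, nperseg=nperseg, axis=-1)
    feats = []
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs < hi)
        feats.append(np.log(psd[..., sel].sum(axis=-1) + 1e-20))
    return np.concatenate(feats, axis=-1)


def bandpower_reference_classifier(
    train: EpochSet,
    test: EpochSet,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    channels: Sequence[int] | None = None,
) -> float:
    """Nearest-class-centroid accuracy on log band-power features.

    Deterministic; serves as a non-neural separability reference for the
    generator (and as the classical band-power baseline the convolutional
    models are meant to supersede).
    """
    ftr = bandpower_features(train, bands, channels)
    fte = bandpower_features(test, bands, channels)
    classes = np.unique(train.labels)
    centroids = np.stack([ftr[train.labels == c].mean(axis=0) for c in classes])
    d2 = ((fte[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=-1)
    pred = classes[np.argmin(d2, axis=1)]
    return float((pred == test.labels).mean())
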