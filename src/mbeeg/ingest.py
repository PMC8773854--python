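"""Adapters from external recording formats to continuous sessions.

BCI Competition IV-2a ships as GDF session files (22 EEG + 3 EOG channels,
250 Hz, cue-annotated trials).  Parsing is delegated to ``mne`` (optional
dependency); this module only owns the output contract: a continuous
signal, its sampling rate, and an ordered list of ``(cue_time, class)``
events with EOG channels removed and dataset event codes mapped to 0-based
class indices.

The dataset's own artifact annotations may be passed through as a keep/drop
mask; no artifact-detection rule of our own is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["SessionRecording", "session_from_arrays", "import_gdf_sessions"]


@dataclass
class SessionRecording:
    """A continuous multichannel recording with cue events.

    ``signal`` is ``(n_channels, n_samples)``; ``events`` is an ordered
    list of ``(cue_time_s, class_index)`` pairs with 0-based classes.
    """

    signal: np.ndarray
    fs: float
    events: list[tuple[float, int]]
    channel_names: list[str] = field(default_factory=list)
    source: str | None = None


def session_from_arrays(
    signal: np.ndarray,
    fs: float,
    channel_names: Sequence[str],
    onsets_s: Sequence[float],
    codes: Sequence[object],
    event_codes: Mapping[int, object],
    keep_mask: Sequence[bool] | None = None,
    exclude_channels: Sequence[str] = ("EOG",),
    source: str | None = None,
) -> SessionRecording:
    """Build a :class:`SessionRecording` from raw arrays and annotations.

    Parameters
    ----------
    signal, fs, channel_names
        Continuous recording; channels whose name contains any of the
        ``exclude_channels`` substrings (case-insensitive) are dropped.
    onsets_s, codes
        Parallel sequences of annotation onsets (seconds) and event codes.
    event_codes
        Mapping ``class_index -> code``; codes found in the annotations
        that are absent from this mapping are skipped with a warning.
    keep_mask
        Optional per-event boolean mask (e.g. the dataset's artifact
        annotations); events with ``False`` are dropped.
    """
    signal = np.asarray(signal)
    if signal.ndim != 2:
        raise ValidationError(f"signal: expected (channels, samples), got ndim={signal.ndim}")
    if len(channel_names) != signal.shape[0]:
        raise ValidationError(
            f"channel_names: {len(channel_names)} names for {signal.shape[0]} channels"
        )
    if len(onsets_s) != len(codes):
        raise ValidationError("onsets_s and codes must have equal length")
    if keep_mask is not None and len(keep_mask) != len(codes):
        raise ValidationError("keep_mask must have one entry per event")

    # drop EOG-style channels
    excl = tuple(s.lower() for s in exclude_channels)
    keep_ch = [i for i, name in enumerate(channel_names) if not any(s in str(name).lower() for s in excl)]
    out_signal = signal[keep_ch]
    out_names = [str(channel_names[i]) for i in keep_ch]

    code_to_class = {str(v): int(k) for k, v in event_codes.items()}
    events: list[tuple[float, int]] = []
    for j, (onset, code) in enumerate(zip(onsets_s, codes)):
        if keep_mask is not None and not keep_mask[j]:
            continue
        cls = code_to_class.get(str(code))
        if cls is None:
            warnings.warn(f"unknown event code {code!r} at {onset:.3f}s; skipped", stacklevel=2)
            continue
        events.append((float(onset), cls))
    events.sort(key=lambda e: e[0])
    return SessionRecording(out_signal, float(fs), events, out_names, source=source)


def import_gdf_sessions(
    session_paths: Sequence[str | Path],
    event_codes: Mapping[int, object],
    keep_masks: Sequence[Sequence[bool]] | None = None,
    exclude_channels: Sequence[str] = ("EOG",),
) -> list[SessionRecording]:
    """Read GDF session files into :class:`SessionRecording` objects.

    Requires ``mne`` (install the ``gdf`` extra).  ``event_codes`` maps
    0-based class indices to the dataset's annotation codes (for BCI IV-2a
    cue codes: ``{0: 769, 1: 770, 2: 771, 3: 772}``; mne exposes them as
    string descriptions, both forms are accepted).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "GDF ingestion requires mne; install the 'gdf' extra (pip install mbeeg[gdf])"
        ) from exc

    sessions = []
    for i, path in enumerate(session_paths):
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
        sessions.append(
            session_from_arrays(
                raw.get_data(),
                raw.info["sfreq"],
                list(raw.ch_names),
                list(raw.annotations.onset),
                list(raw.annotations.description),
                event_codes,
                keep_mask=None if keep_masks is None else keep_masks[i],
                exclude_channels=exclude_channels,
                source=str(path),
            )
        )
    return sessions
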