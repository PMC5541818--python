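"""Continuous-EEG preprocessing: band-pass, downsample, epoch, baseline.

The chain mirrors a standard P300 pipeline: zero-phase 0.5-60 Hz band-pass on
the continuous data, anti-aliased resampling to 600 Hz, extraction of 1000 ms
stimulus-locked epochs (one per stimulus event, on every stream), and baseline
correction against the 200 ms preceding each stimulus onset.  At a 4 Hz flash
rate the 1 s epochs of neighbouring stimuli overlap by construction; no
overlap-based rejection is performed.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .schedule import RsvpSchedule
from .synth import RawRecording

__all__ = [
    "EpochSet",
    "bandpass_filter",
    "downsample",
    "extract_epochs",
    "baseline_correct",
    "preprocess_chain",
    "save_epochs",
    "load_epochs",
]

log = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Stimulus-locked epochs with labels and provenance tags.

    ``data`` is (epochs, channels, samples) in µV and covers only the
    post-stimulus interval; ``pre_data`` optionally holds pre-stimulus samples
    for baseline correction.
    """

    data: np.ndarray
    fs_hz: float
    labels: np.ndarray  # bool per epoch: target / nontarget
    image_ids: np.ndarray
    stream_ids: np.ndarray  # stream name per epoch
    epoch_length_ms: float
    pre_data: np.ndarray | None = None  # (epochs, channels, pre-samples)
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self):
        n = self.data.shape[0]
        for name in ("labels", "image_ids", "stream_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of epochs ({n})")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            fs_hz=self.fs_hz,
            labels=self.labels[mask],
            image_ids=self.image_ids[mask],
            stream_ids=self.stream_ids[mask],
            epoch_length_ms=self.epoch_length_ms,
            pre_data=None if self.pre_data is None else self.pre_data[mask],
            channel_labels=self.channel_labels,
        )


def bandpass_filter(
    raw: RawRecording, low_hz: float = 0.5, high_hz: float = 60.0, order: int = 4
) -> RawRecording:
    """Zero-phase Butterworth band-pass of the continuous recording."""
    nyq = raw.fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2 "
            f"(got {low_hz}-{high_hz} Hz at fs={raw.fs_hz})"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="band", fs=raw.fs_hz, output="sos"
    )
    return RawRecording(
        data=signal.sosfiltfilt(sos, raw.data, axis=1),
        fs_hz=raw.fs_hz,
        channel_labels=raw.channel_labels,
        annotations=list(raw.annotations),
    )


def downsample(raw: RawRecording, target_fs_hz: float = 600.0) -> RawRecording:
    """Anti-aliased polyphase resampling; annotation samples are rescaled."""
    if target_fs_hz > raw.fs_hz:
        raise ValueError(
            f"cannot upsample: target {target_fs_hz} Hz > source {raw.fs_hz} Hz"
        )
    if target_fs_hz == raw.fs_hz:
        return raw
    frac = Fraction(target_fs_hz / raw.fs_hz).limit_denominator(1000)
    data = signal.resample_poly(
        raw.data, frac.numerator, frac.denominator, axis=1, padtype="line"
    )
    scale = target_fs_hz / raw.fs_hz
    annotations = [(int(round(s * scale)), e) for s, e in raw.annotations]
    return RawRecording(
        data=data,
        fs_hz=target_fs_hz,
        channel_labels=raw.channel_labels,
        annotations=annotations,
    )


def extract_epochs(
    raw: RawRecording,
    schedule: RsvpSchedule | None = None,
    epoch_length_ms: float = 1000.0,
    pre_ms: float = 200.0,
    dtype=np.float32,
) -> EpochSet:
    """Cut one epoch per stimulus event, labelled target/nontarget.

    Events are taken from the recording's annotations (or regenerated from
    ``schedule`` when given).  Epochs that would run past the end of the
    recording are dropped with a logged warning rather than an error.
    ``pre_ms`` of pre-stimulus data is kept alongside for baseline
    correction; at the very start of the recording the available part is used.
    """
    fs = raw.fs_hz
    n_out = int(round(epoch_length_ms / 1000.0 * fs))
    n_pre = int(round(pre_ms / 1000.0 * fs))
    if schedule is not None:
        events = [
            (int(round(e.onset_s * fs)), e)
            for e in sorted(schedule.events, key=lambda e: (e.onset_s, e.stream))
        ]
    else:
        events = raw.annotations
    if not events:
        raise ValueError("no stimulus events to epoch")

    kept, dropped = [], 0
    for start, e in events:
        if start + n_out <= raw.n_samples and start >= 0:
            kept.append((start, e))
        else:
            dropped += 1
    if dropped:
        log.warning("dropped %d events extending past the recording end", dropped)

    n = len(kept)
    data = np.empty((n, raw.n_channels, n_out), dtype=dtype)
    pre = np.zeros((n, raw.n_channels, n_pre), dtype=dtype)
    labels = np.empty(n, dtype=bool)
    image_ids = np.empty(n, dtype=int)
    streams = np.empty(n, dtype=object)
    for i, (start, e) in enumerate(kept):
        data[i] = raw.data[:, start : start + n_out]
        lo = max(0, start - n_pre)
        if start > lo:
            pre[i, :, n_pre - (start - lo) :] = raw.data[:, lo:start]
        labels[i] = e.is_target
        image_ids[i] = e.image_id
        streams[i] = e.stream
    return EpochSet(
        data=data,
        fs_hz=fs,
        labels=labels,
        image_ids=image_ids,
        stream_ids=streams,
        epoch_length_ms=epoch_length_ms,
        pre_data=pre if n_pre else None,
        channel_labels=raw.channel_labels,
    )


def baseline_correct(
    epochs: EpochSet,
    baseline_window_ms: float = 200.0,
    mode: str = "pre_stimulus",
) -> EpochSet:
    """Subtract a per-epoch, per-channel baseline mean.

    ``pre_stimulus`` (default) averages the ``baseline_window_ms`` of data
    immediately preceding stimulus onset; ``whole_epoch_mean`` subtracts the
    epoch's own mean instead (useful when no pre-stimulus data was kept).
    """
    if mode == "whole_epoch_mean":
        base = epochs.data.mean(axis=2, keepdims=True)
    elif mode == "pre_stimulus":
        if epochs.pre_data is None or epochs.pre_data.shape[2] == 0:
            raise ValueError(
                "no pre-stimulus data available; re-epoch with pre_ms > 0 or "
                "use mode='whole_epoch_mean'"
            )
        n_win = int(round(baseline_window_ms / 1000.0 * epochs.fs_hz))
        if n_win <= 0:
            raise ValueError("baseline window must span at least one sample")
        n_win = min(n_win, epochs.pre_data.shape[2])
        base = epochs.pre_data[:, :, -n_win:].mean(axis=2, keepdims=True)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return EpochSet(
        data=epochs.data - base.astype(epochs.data.dtype),
        fs_hz=epochs.fs_hz,
        labels=epochs.labels,
        image_ids=epochs.image_ids,
        stream_ids=epochs.stream_ids,
        epoch_length_ms=epochs.epoch_length_ms,
        pre_data=epochs.pre_data,
        channel_labels=epochs.channel_labels,
    )


def save_epochs(epochs: EpochSet, directory) -> str:
    """Persist an epoch set as a directory: data tensor(s) + JSON sidecar."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "data.npy", epochs.data)
    if epochs.pre_data is not None:
        np.save(d / "pre_data.npy", epochs.pre_data)
    meta = {
        "fs_hz": epochs.fs_hz,
        "epoch_length_ms": epochs.epoch_length_ms,
        "labels": epochs.labels.astype(int).tolist(),
        "image_ids": epochs.image_ids.tolist(),
        "stream_ids": list(map(str, epochs.stream_ids)),
        "channel_labels": list(epochs.channel_labels),
    }
    (d / "epochs.json").write_text(json.dumps(meta))
    return str(d)


def load_epochs(directory) -> EpochSet:
    import json
    from pathlib import Path

    d = Path(directory)
    meta = json.loads((d / "epochs.json").read_text())
    pre = d / "pre_data.npy"
    return EpochSet(
        data=np.load(d / "data.npy"),
        fs_hz=meta["fs_hz"],
        labels=np.array(meta["labels"], dtype=bool),
        image_ids=np.array(meta["image_ids"], dtype=int),
        stream_ids=np.array(meta["stream_ids"], dtype=object),
        epoch_length_ms=meta["epoch_length_ms"],
        pre_data=np.load(pre) if pre.exists() else None,
        channel_labels=tuple(meta["channel_labels"]),
    )


def preprocess_chain(
    raw: RawRecording,
    schedule: RsvpSchedule | None = None,
    low_hz: float = 0.5,
    high_hz: float = 60.0,
    target_fs_hz: float = 600.0,
    epoch_length_ms: float = 1000.0,
    baseline_window_ms: float = 200.0,
) -> EpochSet:
    """Full chain: band-pass -> downsample -> epoch -> baseline-correct."""
    filtered = bandpass_filter(raw, low_hz, high_hz)
    if target_fs_hz < raw.fs_hz:
        filtered = downsample(filtered, target_fs_hz)
    epochs = extract_epochs(
        filtered, schedule, epoch_length_ms, pre_ms=baseline_window_ms
    )
    return baseline_correct(epochs, baseline_window_ms)
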