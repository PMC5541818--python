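"""Minimal EDF (European Data Format) export/import for recordings.

The writer emits plain EDF: a 256-byte fixed header, one 256-byte signal
header per channel, and contiguous 1-second data records of little-endian
16-bit integers scaled between each channel's physical min/max in µV.  The
reader goes through MNE, so synthetic and real recordings share one loader
and the writer is cross-checked against an independent implementation.

Stimulus events travel in a companion tab-separated table (see
`multirsvp.schedule.write_events`), not inside the EDF.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .synth import RawRecording

__all__ = ["write_edf", "read_edf"]

_RECORD_S = 1.0  # data-record duration


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(raw: RawRecording, path) -> str:
    """Write a recording as 16-bit EDF in physical units of µV.

    The final record is zero-padded to a whole second; quantisation error is
    bounded by the per-channel physical range divided by 2^16.
    """
    fs = raw.fs_hz
    spr = int(round(fs * _RECORD_S))
    if abs(spr - fs * _RECORD_S) > 1e-9:
        raise ValueError("sampling rate must yield integer samples per record")
    n_ch, n_samp = raw.data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = raw.data

    # symmetric physical range per channel, with a floor to avoid zero span
    span = np.maximum(np.abs(padded).max(axis=1), 1e-3)
    phys_min, phys_max = -span, span
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)

    start = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),  # local patient id (anonymous)
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad(start.strftime("%d.%m.%y"), 8),
            _pad(start.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad(f"{_RECORD_S:g}", 8),
            _pad(str(n_ch), 4),
        ]
    )
    sig_fields = [
        (lambda c: f"EEG {raw.channel_labels[c]}", 16),
        (lambda c: "AgAgCl electrode", 80),
        (lambda c: "uV", 8),
        (lambda c: f"{phys_min[c]:.6g}"[:8], 8),
        (lambda c: f"{phys_max[c]:.6g}"[:8], 8),
        (lambda c: str(dig_min), 8),
        (lambda c: str(dig_max), 8),
        (lambda c: "", 80),
        (lambda c: str(spr), 8),
        (lambda c: "", 32),
    ]
    sig_header = b"".join(
        b"".join(_pad(make(c), width) for c in range(n_ch))
        for make, width in sig_fields
    )

    digital = np.rint(
        (padded - phys_min[:, None]) * gain[:, None] + dig_min
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return str(path)


def read_edf(path) -> RawRecording:
    """Load an EDF file into a recording (µV), via MNE's EDF reader."""
    import mne

    mne_raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = mne_raw.get_data() * 1e6  # MNE returns volts
    labels = tuple(
        ch.removeprefix("EEG ").strip() for ch in mne_raw.ch_names
    )
    return RawRecording(
        data=np.asarray(data),
        fs_hz=float(mne_raw.info["sfreq"]),
        channel_labels=labels,
        annotations=[],
    )
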