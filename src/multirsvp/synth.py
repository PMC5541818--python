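"""Synthetic multi-channel EEG with planted, repetition-dependent P300s.

The generator turns a stimulus schedule plus a gaze trace into a continuous
recording: coloured background noise (AR(1)-filtered Gaussian), a 50 Hz mains
component, and — for every target presentation that is attended according to
the gaze model — a Gaussian P300 deflection projected through a fixed scalp
topography.  The deflection's amplitude shrinks and its latency grows with the
repetition index (first/second/third viewing of the same target), emulating
the observer's reduced surprise when a known target reappears.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .schedule import STREAM_NAMES, GazeTrace, RsvpSchedule, StimulusEvent

__all__ = [
    "CHANNELS_16",
    "ErpTemplate",
    "RawRecording",
    "default_template",
    "simulate_recording",
    "attended_presentations",
    "apply_acquisition",
]

#: 16-channel montage (10-20 system); the default P300 topography peaks at Pz.
CHANNELS_16 = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8",
    "C3", "Cz", "C4", "T7", "T8",
    "P3", "Pz", "P4", "Oz",
)

#: Centro-parietal emphasis per channel group, used to build the default
#: topography (arbitrary positive loadings, normalised to unit Euclidean norm).
_P300_LOADINGS = {
    "Fp1": 0.10, "Fp2": 0.10, "F3": 0.20, "Fz": 0.25, "F4": 0.20,
    "F7": 0.10, "F8": 0.10, "C3": 0.45, "Cz": 0.60, "C4": 0.45,
    "T7": 0.15, "T8": 0.15, "P3": 0.70, "Pz": 1.00, "P4": 0.70,
    "Oz": 0.40,
}


@dataclass
class ErpTemplate:
    """Planted P300 shape, by repetition index (1st/2nd/3rd presentation).

    Defaults follow the qualitative picture of repeated target viewings:
    the third response is smaller and later than the first.
    """

    peak_latency_ms: tuple[float, float, float] = (300.0, 300.0, 400.0)
    amplitude_uV: tuple[float, float, float] = (6.0, 5.5, 4.0)
    width_ms: float = 200.0  # Gaussian FWHM
    topography: np.ndarray | None = None  # unit-norm per-channel weights

    def topography_for(self, n_channels: int) -> np.ndarray:
        if self.topography is not None:
            topo = np.asarray(self.topography, dtype=float)
            if topo.shape != (n_channels,):
                raise ValueError(
                    f"topography has {topo.shape} weights for {n_channels} channels"
                )
        elif n_channels == len(CHANNELS_16):
            topo = np.array([_P300_LOADINGS[c] for c in CHANNELS_16])
        else:
            # fall back to a smooth bump centred on the last quarter of
            # the montage (posterior channels by convention)
            x = np.arange(n_channels)
            topo = np.exp(-0.5 * ((x - 0.75 * n_channels) / (n_channels / 4)) ** 2)
        norm = np.linalg.norm(topo)
        if norm == 0:
            raise ValueError("topography must be non-zero")
        return topo / norm


def default_template() -> ErpTemplate:
    return ErpTemplate()


@dataclass
class RawRecording:
    """Continuous multi-channel EEG in microvolts.

    ``annotations`` holds ``(sample_index, StimulusEvent)`` pairs for every
    scheduled stimulus, so epoching never depends on external files.
    """

    data: np.ndarray  # channels x samples, µV
    fs_hz: float
    channel_labels: tuple[str, ...]
    annotations: list[tuple[int, StimulusEvent]] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def attended_presentations(
    schedule: RsvpSchedule, gaze: GazeTrace | None
) -> list[tuple[int, int, int]]:
    """List attended target presentations as ``(base_frame, stream_idx, rep)``.

    ``rep`` is the 0-based repetition index (0 = first viewing, on the left
    stream).  With ``gaze=None`` (or a single-stream schedule) every left
    presentation of a target is attended and later streams are attended in
    order, i.e. ideal compliance with the shift protocol.
    """
    _, is_target = schedule.base_sequence()
    delays = schedule.stream_delay_frames
    out: list[tuple[int, int, int]] = []
    for t in np.flatnonzero(is_target):
        t = int(t)
        if gaze is None:
            for s in range(schedule.n_streams):
                out.append((t, s, s))
            continue
        for s in range(schedule.n_streams):
            tf = t + delays[s]
            if tf < len(gaze.attended):
                seen = gaze.attended[tf] == STREAM_NAMES[s] and gaze.perceiving[tf]
            else:
                seen = False
            if seen:
                out.append((t, s, s))
    return out


def simulate_recording(
    schedule: RsvpSchedule,
    gaze: GazeTrace | None = None,
    template: ErpTemplate | None = None,
    n_channels: int = 16,
    fs_hz: float = 2400.0,
    noise_sd_uV: float = 10.0,
    line_noise_uV: float = 2.0,
    seed: int = 0,
    duration_s: float | None = None,
    ar_coeff: float = 0.95,
    spatial_noise_frac: float = 0.8,
    n_noise_sources: int = 6,
) -> RawRecording:
    """Simulate a continuous EEG recording locked to ``schedule``.

    Background noise per channel is an AR(1) process (coefficient
    ``ar_coeff``) with stationary standard deviation ``noise_sd_uV``.  A
    fraction ``spatial_noise_frac`` of each channel's noise variance comes
    from ``n_noise_sources`` latent AR(1) sources mixed across channels
    (a surrogate for volume conduction, which makes real EEG background
    strongly correlated between electrodes and is what gives spatial
    filtering its leverage); the rest is independent sensor noise.  Set
    ``spatial_noise_frac=0`` for spatially independent noise.  A 50 Hz
    sinusoid of amplitude ``line_noise_uV`` is added on top.

    Each target presentation that is attended per ``gaze`` adds
    ``topography ⊗ Gaussian bump`` at ``onset + peak_latency_ms[rep]``,
    where ``amplitude_uV[rep]`` is the deflection on the topography's
    maximal channel.  Unattended presentations contribute nothing (a missed
    image evokes no P300).  Deterministic given ``seed``.
    """
    if not 0.0 <= spatial_noise_frac <= 1.0:
        raise ValueError("spatial_noise_frac must be in [0, 1]")
    if fs_hz < 600:
        raise ValueError("fs_hz must be >= 600")
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    template = template or default_template()

    needed = schedule.duration_s + 1.5
    if duration_s is None:
        duration_s = needed
    elif duration_s < needed:
        raise ValueError(
            f"requested duration {duration_s:.2f}s is shorter than the "
            f"schedule needs ({needed:.2f}s)"
        )
    n_samples = int(round(duration_s * fs_hz))

    rng = np.random.default_rng(seed)
    labels = CHANNELS_16 if n_channels == 16 else tuple(
        f"EEG{i + 1:02d}" for i in range(n_channels)
    )

    data = np.zeros((n_channels, n_samples))
    if noise_sd_uV > 0:
        innov_sd = noise_sd_uV * np.sqrt(1.0 - ar_coeff**2)
        if spatial_noise_frac > 0 and n_noise_sources > 0:
            sources = signal.lfilter(
                [1.0], [1.0, -ar_coeff],
                rng.standard_normal((n_noise_sources, n_samples)) * innov_sd,
                axis=1,
            )
            mix = rng.standard_normal((n_channels, n_noise_sources))
            mix *= np.sqrt(spatial_noise_frac) / np.linalg.norm(
                mix, axis=1, keepdims=True
            )
            data += mix @ sources
        if spatial_noise_frac < 1:
            white = rng.standard_normal((n_channels, n_samples)) * innov_sd
            data += np.sqrt(1.0 - spatial_noise_frac) * signal.lfilter(
                [1.0], [1.0, -ar_coeff], white, axis=1
            )
    if line_noise_uV > 0:
        t = np.arange(n_samples) / fs_hz
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        data += line_noise_uV * np.sin(
            2 * np.pi * 50.0 * t[None, :] + phases[:, None]
        )

    topo = template.topography_for(n_channels)
    # amplitude_uV is the deflection on the topography's maximal channel
    # (Pz by default); the unit-norm topography sets the spatial direction
    topo = topo / topo.max()
    sigma_s = template.width_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(4 * sigma_s * fs_hz))
    bump_t = np.arange(-half, half + 1) / fs_hz
    bump_shape = np.exp(-0.5 * (bump_t / sigma_s) ** 2)

    delays_s = tuple(d / 1000.0 for d in schedule.stream_delays_ms)
    for base_frame, s, rep in attended_presentations(schedule, gaze):
        onset = base_frame / schedule.flash_rate_hz + delays_s[s]
        peak = onset + template.peak_latency_ms[rep] / 1000.0
        amp = template.amplitude_uV[rep]
        if amp == 0:
            continue
        centre = int(round(peak * fs_hz))
        lo, hi = centre - half, centre + half + 1
        blo, bhi = max(lo, 0), min(hi, n_samples)
        data[:, blo:bhi] += amp * topo[:, None] * bump_shape[blo - lo : bhi - lo]

    annotations = [
        (int(round(e.onset_s * fs_hz)), e)
        for e in sorted(schedule.events, key=lambda e: (e.onset_s, e.stream))
    ]
    return RawRecording(
        data=data, fs_hz=fs_hz, channel_labels=labels, annotations=annotations
    )


def apply_acquisition(
    raw: RawRecording, lowpass_hz: float = 200.0, notch_hz: float = 50.0
) -> RawRecording:
    """Emulate the amplifier's acquisition filters: anti-alias low-pass plus a
    mains notch, both zero-phase.  At 600 Hz and below the 200 Hz low-pass is
    skipped when it would sit at/above Nyquist.
    """
    data = raw.data
    nyq = raw.fs_hz / 2.0
    if lowpass_hz and lowpass_hz < nyq:
        sos = signal.butter(4, lowpass_hz, btype="low", fs=raw.fs_hz, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    if notch_hz:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=raw.fs_hz)
        data = signal.filtfilt(b, a, data, axis=1)
    return RawRecording(
        data=np.ascontiguousarray(data),
        fs_hz=raw.fs_hz,
        channel_labels=raw.channel_labels,
        annotations=list(raw.annotations),
    )
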