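"""Multi-stream RSVP stimulus scheduling and the deterministic gaze model.

A multi-RSVP session presents one base image sequence on the left of the
screen and re-presents the same sequence on the right (and, for triple-RSVP,
bottom) stream after a fixed delay, so an attended target image can be viewed
two or three times.  This module builds such schedules block by block, places
targets uniformly at random subject to a minimum-gap constraint (consecutive
targets in the base sequence are kept apart so that images missed while the
gaze travels between streams are nontargets), and simulates the prescribed
attention-shift protocol: fixate left, follow a detected target to the right
(then bottom) stream, then refixate left.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STREAM_NAMES",
    "StimulusEvent",
    "RsvpSchedule",
    "GazeTrace",
    "ScheduleError",
    "EventsParseError",
    "generate_schedule",
    "derive_gaze",
    "write_events",
    "read_events",
    "default_min_target_gap",
]

#: Stream order also defines the gaze-shift order: left -> right -> bottom.
STREAM_NAMES = ("left", "right", "bottom")


class ScheduleError(ValueError):
    """Raised when schedule parameters are inconsistent or infeasible."""


class EventsParseError(ValueError):
    """Raised when an events table cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class StimulusEvent:
    """One image flash on one stream.

    ``frame_index`` counts frames within the stream's own sequence, so the
    onset is ``frame_index / flash_rate + stream_delay``.
    """

    stream: str
    frame_index: int
    onset_s: float
    image_id: int
    is_target: bool


@dataclass
class RsvpSchedule:
    """A complete timed stimulus schedule for 1-3 simultaneous RSVP streams."""

    events: list[StimulusEvent]
    flash_rate_hz: float
    n_streams: int
    stream_delays_ms: tuple[float, ...]
    n_blocks: int
    images_per_block: int
    targets_per_block: int
    min_target_gap_frames: int
    seed: int
    #: per-target delay jitter (frames) when ``randomize_reappearance`` is on
    reappearance_jitter: dict[int, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_images(self) -> int:
        return self.n_blocks * self.images_per_block

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.flash_rate_hz

    @property
    def stream_delay_frames(self) -> tuple[int, ...]:
        period_ms = 1000.0 / self.flash_rate_hz
        return tuple(int(round(d / period_ms)) for d in self.stream_delays_ms)

    @property
    def streams(self) -> tuple[str, ...]:
        return STREAM_NAMES[: self.n_streams]

    def base_sequence(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(image_ids, is_target)`` of the base (left) sequence."""
        left = sorted(
            (e for e in self.events if e.stream == "left"),
            key=lambda e: e.frame_index,
        )
        ids = np.array([e.image_id for e in left], dtype=int)
        tgt = np.array([e.is_target for e in left], dtype=bool)
        return ids, tgt

    def target_frames(self) -> np.ndarray:
        """Frame indices of targets in the base sequence, ascending."""
        _, tgt = self.base_sequence()
        return np.flatnonzero(tgt)

    def events_for_stream(self, stream: str) -> list[StimulusEvent]:
        return sorted(
            (e for e in self.events if e.stream == stream),
            key=lambda e: e.frame_index,
        )

    @property
    def duration_s(self) -> float:
        return max(e.onset_s for e in self.events) + self.frame_period_s


@dataclass
class GazeTrace:
    """Per-frame attended stream under the deterministic shift protocol.

    ``attended`` has one entry per base-timeline frame (index = elapsed frames
    since the left stream started).  ``perceiving`` is False during the
    refixation travel back to the left stream, when no stream is read.
    """

    attended: np.ndarray  # array of stream names, dtype=object / str
    perceiving: np.ndarray  # bool, same length
    missed_base_frames: list[int]
    refixation_frames: int


def default_min_target_gap(n_streams: int, refixation_frames: int = 3) -> int:
    """Gap that guarantees images missed during gaze shifts are nontargets.

    A diversion triggered by a target at base frame t leaves frames
    t+1 .. t+span+refixation unattended (span = largest stream delay in
    frames), so the next target must lie strictly beyond that window.
    """
    span = 3 * (n_streams - 1)  # default 750 ms steps at 4 Hz
    return span + refixation_frames + 1 if n_streams > 1 else 1


def _place_targets_in_block(
    rng: np.random.Generator,
    n: int,
    k: int,
    gap: int,
    min_first: int,
) -> np.ndarray:
    """Uniform draw of k target positions in [min_first, n) with pairwise
    gaps >= gap (min_first carries the constraint over from the previous
    block).  Uses the standard combination bijection: choose k sorted values
    from the contracted range and re-expand; this is uniform over the
    feasible placements.
    """
    if k == 0:
        return np.empty(0, dtype=int)
    avail = n - min_first
    span = (k - 1) * (gap - 1)
    if avail - span < k:
        raise ScheduleError(
            f"cannot place {k} targets with gap >= {gap} in a block of {n} "
            f"images (first usable frame {min_first})"
        )
    picks = np.sort(rng.choice(avail - span, size=k, replace=False))
    return min_first + picks + np.arange(k) * (gap - 1)


def generate_schedule(
    n_streams: int = 3,
    n_blocks: int = 10,
    images_per_block: int = 200,
    targets_per_block: int = 20,
    flash_rate_hz: float = 4.0,
    stream_delays_ms: tuple[float, ...] | None = None,
    min_target_gap_frames: int | None = None,
    seed: int = 0,
    randomize_reappearance: bool = False,
    reappearance_jitter_frames: int = 2,
) -> RsvpSchedule:
    """Generate a single/dual/triple-RSVP schedule.

    Every stream shows the same image sequence; stream ``s`` is delayed by
    ``stream_delays_ms[s]`` (defaults: 0 / 750 / 1500 ms, i.e. 3-frame steps at
    the 4 Hz flash rate).  Each block of the base sequence contains exactly
    ``targets_per_block`` targets, placed uniformly among positions whose
    pairwise frame gaps are at least ``min_target_gap_frames`` (the constraint
    also binds across block boundaries).  Deterministic given ``seed``.

    With ``randomize_reappearance`` the per-target delay on the later streams
    is jittered by up to ``reappearance_jitter_frames`` frames so the observer
    cannot anticipate the exact reappearance time; off by default.
    """
    if n_streams not in (1, 2, 3):
        raise ScheduleError(f"n_streams must be 1, 2 or 3, got {n_streams}")
    if targets_per_block > images_per_block:
        raise ScheduleError("targets_per_block exceeds images_per_block")
    if stream_delays_ms is None:
        stream_delays_ms = tuple(750.0 * s for s in range(n_streams))
    stream_delays_ms = tuple(float(d) for d in stream_delays_ms)
    if len(stream_delays_ms) != n_streams:
        raise ScheduleError("stream_delays_ms length must equal n_streams")
    if stream_delays_ms[0] != 0.0:
        raise ScheduleError("the left (base) stream delay must be 0")
    period_ms = 1000.0 / flash_rate_hz
    for d in stream_delays_ms:
        if abs(d / period_ms - round(d / period_ms)) > 1e-9:
            raise ScheduleError(
                f"stream delay {d} ms is not a multiple of the frame period "
                f"({period_ms:g} ms)"
            )
    if min_target_gap_frames is None:
        min_target_gap_frames = default_min_target_gap(n_streams)
    if min_target_gap_frames < 1:
        raise ScheduleError("min_target_gap_frames must be >= 1")
    if targets_per_block * min_target_gap_frames > images_per_block:
        raise ScheduleError(
            f"gap constraint infeasible: {targets_per_block} targets x gap "
            f"{min_target_gap_frames} > {images_per_block} images per block"
        )

    rng = np.random.default_rng(seed)
    n_images = n_blocks * images_per_block
    is_target = np.zeros(n_images, dtype=bool)
    prev_last = -min_target_gap_frames  # no carry-over before the first block
    for b in range(n_blocks):
        start = b * images_per_block
        min_first = max(0, prev_last + min_target_gap_frames - start)
        pos = _place_targets_in_block(
            rng, images_per_block, targets_per_block, min_target_gap_frames,
            min_first,
        )
        is_target[start + pos] = True
        if len(pos):
            prev_last = start + pos[-1]

    delay_frames = tuple(int(round(d / period_ms)) for d in stream_delays_ms)
    jitter: dict[int, tuple[int, ...]] = {}
    if randomize_reappearance and n_streams > 1:
        for f in np.flatnonzero(is_target):
            jitter[int(f)] = tuple(
                int(rng.integers(0, reappearance_jitter_frames + 1))
                for _ in range(n_streams - 1)
            )

    events: list[StimulusEvent] = []
    for s, name in enumerate(STREAM_NAMES[:n_streams]):
        delay_s = stream_delays_ms[s] / 1000.0
        for f in range(n_images):
            extra = 0
            if s > 0 and int(f) in jitter:
                extra = jitter[int(f)][s - 1]
            events.append(
                StimulusEvent(
                    stream=name,
                    frame_index=f + extra,
                    onset_s=(f + extra) / flash_rate_hz + delay_s,
                    image_id=f,
                    is_target=bool(is_target[f]),
                )
            )

    return RsvpSchedule(
        events=events,
        flash_rate_hz=flash_rate_hz,
        n_streams=n_streams,
        stream_delays_ms=stream_delays_ms,
        n_blocks=n_blocks,
        images_per_block=images_per_block,
        targets_per_block=targets_per_block,
        min_target_gap_frames=min_target_gap_frames,
        seed=seed,
        reappearance_jitter=jitter,
    )


def derive_gaze(schedule: RsvpSchedule, refixation_frames: int = 3) -> GazeTrace:
    """Simulate the deterministic attention-shift protocol.

    The observer fixates the left stream.  When an attended left frame is a
    target, attention follows the image: it dwells on the right stream until
    the same target reappears there (the inter-stream delay), then — for
    triple-RSVP — on the bottom stream until the third appearance, and finally
    travels back to the left stream for ``refixation_frames`` frames during
    which nothing is perceived.  A base image is *missed* when none of its
    presentations falls on an attended, perceived stream.  Targets appearing
    inside a diversion window are missed silently and trigger no shift.

    For a single-stream schedule the gaze never leaves the left stream and the
    missed list is empty.
    """
    ids, is_target = schedule.base_sequence()
    n = len(ids)
    delays = schedule.stream_delay_frames
    span = delays[-1] if schedule.n_streams > 1 else 0
    horizon = n + span + refixation_frames + 1

    attended = np.full(horizon, "left", dtype=object)
    perceiving = np.ones(horizon, dtype=bool)

    if schedule.n_streams > 1:
        t = 0
        while t < n:
            if attended[t] == "left" and perceiving[t] and is_target[t]:
                # dwell on each later stream until the target reappears there
                for s in range(1, schedule.n_streams):
                    lo, hi = t + delays[s - 1] + 1, t + delays[s] + 1
                    attended[lo:hi] = STREAM_NAMES[s]
                lo = t + span + 1
                attended[lo : lo + refixation_frames] = "left"
                perceiving[lo : lo + refixation_frames] = False
                t = lo + refixation_frames
            else:
                t += 1

    missed: list[int] = []
    for f in range(n):
        seen = attended[f] == "left" and perceiving[f]
        for s in range(1, schedule.n_streams):
            tf = f + delays[s]
            seen = seen or (
                tf < horizon and attended[tf] == STREAM_NAMES[s] and perceiving[tf]
            )
        if not seen:
            missed.append(f)

    return GazeTrace(
        attended=attended[:n],
        perceiving=perceiving[:n],
        missed_base_frames=missed,
        refixation_frames=refixation_frames,
    )


# ---------------------------------------------------------------------------
# Events table I/O (BIDS-style TSV)

_EVENT_COLUMNS = ("onset", "duration", "stream", "image_id", "is_target")


def write_events(schedule: RsvpSchedule, path) -> str:
    """Write the schedule's events as a tab-separated table.

    Columns: onset (s, 6 decimals), duration (s), stream, image_id,
    is_target (0/1).  Rows are sorted by onset then stream.
    """
    duration = schedule.frame_period_s
    rows = sorted(schedule.events, key=lambda e: (e.onset_s, e.stream))
    with open(path, "w") as fh:
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for e in rows:
            fh.write(
                f"{e.onset_s:.6f}\t{duration:.6f}\t{e.stream}\t"
                f"{e.image_id}\t{int(e.is_target)}\n"
            )
    return str(path)


def read_events(path, flash_rate_hz: float | None = None) -> RsvpSchedule:
    """Read an events table back into a schedule.

    The flash rate and stream delays are inferred from the onsets unless the
    flash rate is given.  Block bookkeeping cannot be recovered from the table
    alone, so the result carries a single block spanning the whole sequence.
    """
    events: list[StimulusEvent] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _EVENT_COLUMNS:
            raise EventsParseError(
                f"expected header {list(_EVENT_COLUMNS)}, got {header}", 1
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_EVENT_COLUMNS):
                raise EventsParseError(
                    f"expected {len(_EVENT_COLUMNS)} columns, got {len(parts)}",
                    lineno,
                )
            try:
                onset = float(parts[0])
                stream = parts[2]
                image_id = int(parts[3])
                is_target = bool(int(parts[4]))
            except ValueError as exc:
                raise EventsParseError(str(exc), lineno) from None
            if onset < 0:
                raise EventsParseError(f"negative onset {onset}", lineno)
            if stream not in STREAM_NAMES:
                raise EventsParseError(f"unknown stream {stream!r}", lineno)
            events.append(
                StimulusEvent(
                    stream=stream,
                    frame_index=0,  # filled in below
                    onset_s=onset,
                    image_id=image_id,
                    is_target=is_target,
                )
            )

    if not events:
        raise EventsParseError("no event rows", 2)

    streams = [s for s in STREAM_NAMES if any(e.stream == s for e in events)]
    delays_s = {s: min(e.onset_s for e in events if e.stream == s) for s in streams}
    if flash_rate_hz is None:
        left_onsets = sorted(e.onset_s for e in events if e.stream == "left")
        if len(left_onsets) < 2:
            raise EventsParseError("cannot infer flash rate from < 2 events", 2)
        period = min(b - a for a, b in zip(left_onsets, left_onsets[1:]))
        flash_rate_hz = 1.0 / period
    fixed = [
        replace(
            e,
            frame_index=int(round((e.onset_s - delays_s[e.stream]) * flash_rate_hz)),
        )
        for e in events
    ]
    n_images = max(e.frame_index for e in fixed if e.stream == "left") + 1
    n_targets = sum(1 for e in fixed if e.stream == "left" and e.is_target)
    return RsvpSchedule(
        events=fixed,
        flash_rate_hz=flash_rate_hz,
        n_streams=len(streams),
        stream_delays_ms=tuple(delays_s[s] * 1000.0 for s in streams),
        n_blocks=1,
        images_per_block=n_images,
        targets_per_block=n_targets,
        min_target_gap_frames=1,
        seed=-1,
    )
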