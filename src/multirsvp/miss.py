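"""Target-miss probability of the multi-RSVP gaze protocol.

While the observer's gaze follows a detected target from the left stream to
the right (and bottom) stream and back, N base-sequence images go unread.
If targets occur independently with probability p, the chance that at least
one of those N ignored images is itself a target is

    P_miss = 1 - (1 - p)**N .

This closed form is the per-diversion miss probability.  It is distinct from
the long-run *fraction of target images* that end up missed, which under a
renewal argument is N·p / (1 + N·p): each cycle consists of one attended
target plus N ignored frames holding on average N·p further targets.  Both
quantities are exposed; schedule-level estimators validate them empirically.
"""

from __future__ import annotations

import numpy as np

from .schedule import GazeTrace, RsvpSchedule, derive_gaze

__all__ = [
    "miss_probability",
    "expected_target_miss_fraction",
    "simulate_miss_rate",
    "schedule_miss_rate",
    "schedule_diversion_miss_rate",
    "default_n_ignored",
]


def default_n_ignored(n_streams: int, refixation_frames: int = 3) -> int:
    """Images ignored per diversion: stream-delay span + refixation frames
    (6 for dual-, 9 for triple-RSVP at the default 3-frame delays)."""
    return 3 * (n_streams - 1) + refixation_frames if n_streams > 1 else 0


def miss_probability(p_target: float, n_ignored: int) -> float:
    """Closed-form probability that a diversion skips at least one target."""
    if not 0.0 <= p_target <= 1.0:
        raise ValueError(f"p_target must be in [0, 1], got {p_target}")
    if n_ignored < 0 or int(n_ignored) != n_ignored:
        raise ValueError(f"n_ignored must be a nonnegative integer, got {n_ignored}")
    return 1.0 - (1.0 - p_target) ** int(n_ignored)


def expected_target_miss_fraction(p_target: float, n_ignored: int) -> float:
    """Long-run fraction of target images missed: N·p / (1 + N·p)."""
    if not 0.0 <= p_target <= 1.0:
        raise ValueError(f"p_target must be in [0, 1], got {p_target}")
    np_ = n_ignored * p_target
    return np_ / (1.0 + np_)


def simulate_miss_rate(
    p_target: float,
    n_ignored_per_event: int,
    n_trials: int = 10**6,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the per-diversion miss probability.

    Each trial draws ``n_ignored_per_event`` independent Bernoulli(p) images
    and records whether any is a target.  Returns ``(estimate, standard
    error)``; the estimate agrees with `miss_probability` to within MC error.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_ignored_per_event == 0 or p_target == 0.0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    hits = np.zeros(n_trials, dtype=bool)
    chunk = max(1, 10**7 // max(n_ignored_per_event, 1))
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        draws = rng.random((hi - lo, n_ignored_per_event)) < p_target
        hits[lo:hi] = draws.any(axis=1)
    est = float(hits.mean())
    se = float(np.sqrt(max(est * (1 - est), 1e-12) / n_trials))
    return est, se


def _diversion_windows(schedule: RsvpSchedule, gaze: GazeTrace):
    """Ignored-frame window of each gaze diversion.

    A diversion is triggered by a target attended on the left stream; the
    ignored window spans the following ``span + refixation`` base frames
    (span = largest stream delay in frames), matching the closed-form
    model's premise of N ignored images per transfer.
    """
    _, is_target = schedule.base_sequence()
    span = schedule.stream_delay_frames[-1]
    width = span + gaze.refixation_frames
    n = len(gaze.attended)
    windows = []
    for t in np.flatnonzero(is_target):
        if gaze.attended[t] == "left" and gaze.perceiving[t]:
            windows.append((t + 1, min(t + 1 + width, n)))
    return windows


def schedule_miss_rate(
    schedule: RsvpSchedule, gaze: GazeTrace | None = None
) -> float:
    """Empirical fraction of target images missed under the gaze protocol.

    With the default target-gap constraint this is exactly 0 (missed images
    are nontargets by construction).  With the constraint relaxed it
    converges to N·p / (1 + N·p) as the sequence grows — not to the
    per-diversion formula, which `schedule_diversion_miss_rate` estimates.
    """
    if gaze is None:
        gaze = derive_gaze(schedule) if schedule.n_streams > 1 else None
    if gaze is None:
        return 0.0
    _, is_target = schedule.base_sequence()
    n_targets = int(is_target.sum())
    if n_targets == 0:
        raise ValueError("schedule has no targets")
    missed_targets = sum(
        1 for f in gaze.missed_base_frames if is_target[f]
    )
    return missed_targets / n_targets


def schedule_diversion_miss_rate(
    schedule: RsvpSchedule, gaze: GazeTrace | None = None
) -> float:
    """Fraction of gaze diversions during which >= 1 target was skipped.

    This is the schedule-level empirical counterpart of the closed form
    ``1 - (1 - p)**N`` (targets approximately independent when the gap
    constraint is relaxed to 1).
    """
    if gaze is None:
        if schedule.n_streams < 2:
            return 0.0
        gaze = derive_gaze(schedule)
    _, is_target = schedule.base_sequence()
    windows = _diversion_windows(schedule, gaze)
    if not windows:
        return 0.0
    with_target = sum(1 for lo, hi in windows if is_target[lo:hi].any())
    return with_target / len(windows)
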