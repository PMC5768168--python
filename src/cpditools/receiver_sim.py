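"""Waveform-free simulation of coded ping trains and blanking-interval decoding.

A transmission is a train of (by default eight) pings whose inter-ping
intervals carry the code: the first interval is the synchronization interval,
the middle ones the tag ID, the last the checksum.  The receiver registers a
ping, opens a blanking interval during which further arrivals are ignored,
and accepts the transmission only if it registers exactly the expected number
of pings with the expected interval pattern.  A reflected copy of a ping
arriving after the blanking interval, loud enough to clear the detection
threshold, is registered as a spurious ping and invalidates the train — the
mechanism behind CPDI.

The module also provides a Monte-Carlo model of transmission collisions
between multiple tags with variable transmission intervals: overlapping
trains from two tags are both rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .geometry import MultipathArrival, ReceiverSpec

__all__ = [
    "PingTrain",
    "ArrivalEvent",
    "DecodeOutcome",
    "FailureMode",
    "make_ping_train",
    "random_code_intervals",
    "impulse_response",
    "superpose",
    "decode",
    "simulate_collisions",
    "pairwise_overlap_probability",
]

DIRECT = "direct"


class FailureMode(Enum):
    NONE = "none"
    SPURIOUS_PING = "spurious_ping"
    INTERVAL_MISMATCH = "interval_mismatch"
    MISSING_PING = "missing_ping"
    COLLISION = "collision"


@dataclass(frozen=True)
class PingTrain:
    """One coded transmission: strictly increasing ping emission times (s)."""

    ping_times: tuple[float, ...]

    @property
    def intervals(self) -> tuple[float, ...]:
        return tuple(np.diff(self.ping_times))

    @property
    def duration(self) -> float:
        return self.ping_times[-1] - self.ping_times[0]

    @property
    def sync_interval(self) -> float:
        return self.intervals[0]

    @property
    def checksum_interval(self) -> float:
        return self.intervals[-1]


@dataclass(frozen=True)
class ArrivalEvent:
    """One acoustic arrival at the receiver."""

    time: float
    amplitude: float
    source_ping: int
    path: str | MultipathArrival = DIRECT

    @property
    def is_direct(self) -> bool:
        return self.path == DIRECT


@dataclass(frozen=True)
class DecodeOutcome:
    detected: bool
    registered_times: tuple[float, ...]
    failure_mode: FailureMode

    def __post_init__(self) -> None:
        if self.detected and self.failure_mode is not FailureMode.NONE:
            raise ValueError("a detected outcome cannot carry a failure mode")


def make_ping_train(
    spec: ReceiverSpec, code_intervals: Sequence[float], start_time: float = 0.0
) -> PingTrain:
    """Build a ping train from its inter-ping code intervals.

    Intervals must each exceed the blanking interval (a shorter one would be
    swallowed by the receiver's own blanking — the code would self-blank).
    """
    if len(code_intervals) != spec.pings_per_train - 1:
        raise ValueError(
            f"expected {spec.pings_per_train - 1} code intervals, got {len(code_intervals)}"
        )
    bad = [iv for iv in code_intervals if iv <= spec.blanking_interval]
    if bad:
        raise ValueError(
            f"code intervals {bad} do not exceed the blanking interval "
            f"({spec.blanking_interval} s); the train would self-blank"
        )
    times = start_time + np.concatenate([[0.0], np.cumsum(code_intervals)])
    return PingTrain(ping_times=tuple(float(t) for t in times))


def random_code_intervals(
    spec: ReceiverSpec,
    rng: np.random.Generator,
    low: float = 0.3,
    high: float = 0.7,
) -> np.ndarray:
    """Placeholder code intervals, uniform on [low, high) s (the real coding
    scheme is proprietary; sync-first / checksum-last roles are positional)."""
    return rng.uniform(low, high, size=spec.pings_per_train - 1)


def impulse_response(
    arrivals: Sequence[MultipathArrival],
    direct_length: float,
    unit_amplitude: bool = False,
) -> list[tuple[float, float]]:
    """Channel impulse response as (delay s, amplitude) pairs.

    The first entry is the direct arrival at delay 0 with amplitude
    ``1/direct_length``; each multipath contributes ``(delay, 1/L)``.  No
    extra attenuation is applied for surface/seafloor reflection losses.
    With ``unit_amplitude`` the direct amplitude is fixed at 1.0 (required
    when tag and receiver are colocated and the direct length is 0).
    """
    if direct_length <= 0 and not unit_amplitude:
        raise ValueError(
            "direct_length is 0 so 1/L amplitudes are undefined; "
            "pass unit_amplitude=True to use a unit direct amplitude"
        )
    direct_amp = 1.0 if unit_amplitude else 1.0 / direct_length
    ir = [(0.0, direct_amp)]
    ir.extend((a.relative_delay, a.amplitude_scalar) for a in arrivals)
    return ir


def superpose(train: PingTrain, ir: Sequence[tuple[float, float]]) -> list[ArrivalEvent]:
    """Convolve a ping train with an impulse response.

    One event per (ping, impulse-response entry), sorted by arrival time with
    a stable (ping index, entry index) tie-break.
    """
    if not train.ping_times or not ir:
        raise ValueError("train and impulse response must be non-empty")
    events = [
        ArrivalEvent(
            time=t + delay,
            amplitude=amp,
            source_ping=i,
            path=DIRECT if k == 0 else f"multipath[{k}]",
        )
        for i, t in enumerate(train.ping_times)
        for k, (delay, amp) in enumerate(ir)
    ]
    events.sort(key=lambda e: (e.time, e.source_ping, 0 if e.is_direct else 1))
    return events


def decode(
    events: Sequence[ArrivalEvent],
    spec: ReceiverSpec,
    expected_intervals: Sequence[float],
    threshold: float = 0.0,
    tolerance: float = 0.005,
    rearm_on_blanked: bool = False,
) -> DecodeOutcome:
    """Sweep arrivals through the blanking-interval receiver logic.

    An event registers iff its amplitude clears ``threshold`` and it lands at
    or after the end of the current blanking interval.  By default a blanked
    arrival does not restart the blanking clock (``rearm_on_blanked``
    switches that behaviour on).  The transmission is detected iff exactly
    ``pings_per_train`` events register and consecutive registered intervals
    match ``expected_intervals`` within ``tolerance``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    times = [e.time for e in events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("events must be sorted by time")

    registered: list[ArrivalEvent] = []
    last = -math.inf
    for ev in events:
        if ev.amplitude < threshold:
            continue
        if ev.time >= last + spec.blanking_interval:
            registered.append(ev)
            last = ev.time
        elif rearm_on_blanked:
            last = ev.time

    reg_times = tuple(e.time for e in registered)
    n = len(registered)
    intervals_ok = False
    if n == spec.pings_per_train:
        gaps = np.diff(reg_times)
        intervals_ok = bool(
            np.all(np.abs(gaps - np.asarray(expected_intervals)) <= tolerance)
        )
    if n == spec.pings_per_train and intervals_ok:
        return DecodeOutcome(True, reg_times, FailureMode.NONE)
    if any(not e.is_direct for e in registered) or n > spec.pings_per_train:
        mode = FailureMode.SPURIOUS_PING
    elif n < spec.pings_per_train:
        mode = FailureMode.MISSING_PING
    else:
        mode = FailureMode.INTERVAL_MISMATCH
    return DecodeOutcome(False, reg_times, mode)


def pairwise_overlap_probability(
    train_duration: float, interval_window: tuple[float, float]
) -> float:
    """Probability one transmission overlaps a single other tag's trains.

    Other-tag train starts form a renewal process with mean spacing equal to
    the window mean; a train of duration ``d`` is hit when another start
    falls within ``2d`` of its own, so p ~= 2d / mean_interval.
    """
    mean_interval = 0.5 * (interval_window[0] + interval_window[1])
    return min(1.0, 2.0 * train_duration / mean_interval)


def simulate_collisions(
    n_tags: int,
    interval_window: tuple[float, float] = (30.0, 90.0),
    train_duration: float = 3.5,
    hours: int = 1,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo transmission collisions among independently pinging tags.

    Each tag emits trains whose start-to-start spacing is uniform on
    ``interval_window``.  A transmission survives iff its
    ``[start, start + duration]`` window overlaps no other tag's train (an
    overlap rejects both transmissions).  Returns
    ``(mean surviving detections per hour, mean per-tag surviving fraction)``.
    """
    if n_tags < 1:
        raise ValueError("n_tags must be >= 1")
    lo, hi = interval_window
    if not 0 < lo <= hi:
        raise ValueError(f"interval window must be positive, got {interval_window}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    horizon = hours * 3600.0

    starts, owners = [], []
    for tag in range(n_tags):
        t = rng.uniform(0.0, hi)
        while t < horizon:
            starts.append(t)
            owners.append(tag)
            t += rng.uniform(lo, hi)
    starts = np.asarray(starts)
    owners = np.asarray(owners)
    order = np.argsort(starts, kind="stable")
    starts, owners = starts[order], owners[order]

    lost = np.zeros(starts.size, dtype=bool)
    n = starts.size
    for i in range(n):
        j = i + 1
        while j < n and starts[j] - starts[i] < train_duration:
            if owners[j] != owners[i]:
                lost[i] = lost[j] = True
            j += 1

    survived = ~lost
    mean_per_hour = survived.sum() / hours
    fractions = [
        survived[owners == tag].mean() if (owners == tag).any() else 1.0
        for tag in range(n_tags)
    ]
    return float(mean_per_hour), float(np.mean(fractions))
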