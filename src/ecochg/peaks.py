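"""Streaming detection of local peaks/troughs and promotion to active peaks.

A local peak in the CM amplitude series is confirmed one sample after it
occurs: ``amp[t-2] < amp[t-1]`` and ``amp[t-1] >= amp[t]`` makes ``t-1`` a
peak; the mirrored condition (``>=`` then ``<``) makes it a trough.  Each peak
is paired with the most recent prior trough (the stream's first sample stands
in before any trough is seen).

Not every local peak is meaningful on a fluctuating amplitude trace.  A peak
is promoted to the *active peak* — the reference against which drops are
judged — when any of three rules fires:

a. no active peak exists yet;
b. the peak exceeds the current active peak;
c. the peak exceeds ``s_a`` times the current active peak AND its prominence
   over the paired trough exceeds ``s_b`` times the peak amplitude.

``s_a = 0.5`` and ``s_b = 0.1`` are empirically chosen defaults.  The tracker
is strictly causal and never rewrites past events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["PeakEvent", "PeakTracker", "track_series", "active_peak_series"]


@dataclass(frozen=True)
class PeakEvent:
    """One detector event.

    ``kind`` is ``'local_peak'``, ``'trough'`` or ``'active_peak'``; ``t`` and
    ``amp`` locate it in the series.  Active-peak events carry the promotion
    ``rule`` ('a'/'b'/'c') and the paired trough.  ``emitted_at`` is the index
    whose arrival triggered the event (always ``t + 1``: one-sample latency).
    """

    kind: str
    t: int
    amp: float
    emitted_at: int
    rule: str | None = None
    trough: tuple[int, float] | None = None


class PeakTracker:
    """Online peak/trough detector with active-peak promotion.

    Feed strictly increasing time indices through :meth:`update`; each call
    returns the events confirmed by that sample.
    """

    def __init__(self, s_a: float = 0.5, s_b: float = 0.1) -> None:
        if not (0 < s_a < 1 and 0 < s_b < 1):
            raise ValueError("s_a and s_b must lie in (0, 1)")
        self.s_a = s_a
        self.s_b = s_b
        self.last_trough: tuple[int, float] | None = None
        self.active_peak: tuple[int, float] | None = None
        self._buf: list[tuple[int, float]] = []  # up to 3 most recent samples

    def update(self, t: int, amp: float) -> list[PeakEvent]:
        """Process the amplitude at time ``t``; return newly confirmed events."""
        if self._buf and t <= self._buf[-1][0]:
            raise ValueError(f"time index must be strictly increasing, got {t}")
        if not self._buf:
            # before any trough is confirmed, the first sample is the running
            # minimum and serves as the pairing trough
            self.last_trough = (t, amp)
        self._buf.append((t, amp))
        if len(self._buf) > 3:
            self._buf.pop(0)
        if len(self._buf) < 3:
            return []

        (t0, a0), (t1, a1), (t2, a2) = self._buf
        events: list[PeakEvent] = []
        if a0 < a1 and a1 >= a2:
            events.extend(self._on_local_peak(t1, a1, emitted_at=t2))
        elif a0 >= a1 and a1 < a2:
            self.last_trough = (t1, a1)
            events.append(PeakEvent("trough", t1, a1, emitted_at=t2))
        return events

    def _on_local_peak(self, t: int, amp: float, emitted_at: int) -> list[PeakEvent]:
        trough = self.last_trough
        events = [PeakEvent("local_peak", t, amp, emitted_at, trough=trough)]
        rule = None
        if self.active_peak is None:
            rule = "a"
        elif amp > self.active_peak[1]:
            rule = "b"
        elif amp > self.s_a * self.active_peak[1] and trough is not None and (
            amp - trough[1]
        ) > self.s_b * amp:
            rule = "c"
        if rule is not None:
            self.active_peak = (t, amp)
            events.append(
                PeakEvent("active_peak", t, amp, emitted_at, rule=rule, trough=trough)
            )
        return events


def track_series(
    amps: Sequence[float] | np.ndarray, s_a: float = 0.5, s_b: float = 0.1
) -> list[PeakEvent]:
    """Run the streaming tracker over a whole amplitude series."""
    tracker = PeakTracker(s_a=s_a, s_b=s_b)
    events: list[PeakEvent] = []
    for t, amp in enumerate(np.asarray(amps, dtype=float)):
        events.extend(tracker.update(t, float(amp)))
    return events


def active_peak_series(
    amps: Sequence[float] | np.ndarray, s_a: float = 0.5, s_b: float = 0.1
) -> list[tuple[int, float] | None]:
    """Causal active-peak reference at each index.

    Entry ``t`` is the ``(t_pk, amp_pk)`` of the active peak known after the
    sample at ``t`` has been processed (promotions confirmed at or before
    ``t``), or None before the first promotion.
    """
    tracker = PeakTracker(s_a=s_a, s_b=s_b)
    out: list[tuple[int, float] | None] = []
    for t, amp in enumerate(np.asarray(amps, dtype=float)):
        tracker.update(t, float(amp))
        out.append(tracker.active_peak)
    return out
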