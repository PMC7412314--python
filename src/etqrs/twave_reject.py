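"""Tall-T-wave rejection via the running mean RR interval.

A tall T wave can pass the threshold stage as a second candidate within
the same beat.  Whenever two successive candidates are closer than
mean(RR)/K (K = 3 by default), only the one with the larger feature
value is kept; the other is discarded as a T wave.  The rule stays
inactive until at least two RR intervals have been observed.

Note the comparison direction: rejection fires when the interval is
*smaller* than mean(RR)/K.  Read the other way round, nearly every
normal interval would trigger rejection, which contradicts the rule's
purpose; a ``literal`` flag preserves the inverted comparison for
side-by-side study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["RrTracker", "Beat", "update_mean_rr", "resolve_tall_t"]


@dataclass(frozen=True)
class RrTracker:
    """Running arithmetic mean of accepted RR intervals (in samples)."""

    mean_rr: float = 0.0
    interval_count: int = 0
    k_divisor: float = 3.0

    @property
    def active(self) -> bool:
        return self.interval_count >= 2

    @property
    def cutoff(self) -> float:
        """Intervals below this are treated as QRS/T-wave pairs."""
        return self.mean_rr / self.k_divisor


@dataclass(frozen=True)
class Beat:
    index: int
    feature: float


def update_mean_rr(tracker: RrTracker, new_interval: float) -> RrTracker:
    if not new_interval > 0:
        raise ValueError("RR interval must be positive")
    total = tracker.mean_rr * tracker.interval_count + new_interval
    n = tracker.interval_count + 1
    return replace(tracker, mean_rr=total / n, interval_count=n)


def resolve_tall_t(
    prev_beat: Beat,
    new_candidate: Beat,
    tracker: RrTracker,
    literal: bool = False,
) -> tuple[Beat, ...]:
    """Decide which of two successive candidates survive.

    Returns the kept beats in time order (both, or the winner alone).
    Ties in feature value keep the earlier candidate, which precedes its
    own T wave.
    """
    if new_candidate.index <= prev_beat.index:
        raise ValueError("candidates must be in strictly ascending order")
    if not tracker.active:
        return (prev_beat, new_candidate)
    interval = new_candidate.index - prev_beat.index
    fires = interval > tracker.cutoff if literal else interval < tracker.cutoff
    if not fires:
        return (prev_beat, new_candidate)
    if new_candidate.feature > prev_beat.feature:
        return (new_candidate,)
    return (prev_beat,)
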