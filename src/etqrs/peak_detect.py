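"""Extreme-point detection in fixed, consecutive analysis windows.

The record is tiled with non-overlapping windows of 260 ms (93 samples
at 360 Hz).  Within each window — extended by half a QRS width of
context on both sides so boundary peaks are not missed — a point n is an
extreme iff

    (f(n) - f(n+j)) * (f(n) - f(n-j)) > 0   for every j = 1..half_q,

i.e. it strictly dominates (or is dominated by) both neighbours at every
lag in the QRS-scale neighbourhood.  Points whose neighbourhood leaves
the record are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import FilteredSignal

__all__ = ["WindowPlan", "ExtremeSet", "plan_windows", "find_extremes",
           "window_samples_for_fs", "extreme_mask"]

DEFAULT_WINDOW_MS = 260.0


def window_samples_for_fs(fs: float, window_ms: float = DEFAULT_WINDOW_MS) -> int:
    """floor(window_ms * fs); 93 samples at 360 Hz."""
    return int(math.floor(window_ms / 1000.0 * fs))


@dataclass(frozen=True)
class WindowPlan:
    """One analysis window: [origin, origin + length) plus side context."""

    origin: int
    length: int
    context: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("window length must be >= 1")


@dataclass(frozen=True)
class ExtremeSet:
    """Per-window extreme-point indices (filtered-signal coordinates)."""

    windows: tuple[np.ndarray, ...]

    def __len__(self) -> int:
        return len(self.windows)


def plan_windows(
    record_length: int,
    fs: float,
    window_ms: float = DEFAULT_WINDOW_MS,
    context: int = 0,
) -> list[WindowPlan]:
    """Tile [0, record_length) with consecutive windows; last may be partial."""
    w = window_samples_for_fs(fs, window_ms)
    if record_length <= w:
        raise ValueError(
            f"record length {record_length} does not cover one window ({w})"
        )
    plans = []
    for origin in range(0, record_length, w):
        length = min(w, record_length - origin)
        plans.append(WindowPlan(origin, length, context))
    return plans


def extreme_mask(values: np.ndarray, half_q: int) -> np.ndarray:
    """Boolean mask of the extreme-point criterion over a whole array.

    Vectorized over all positions; positions closer than half_q to either
    end are False.
    """
    f = np.asarray(values, dtype=np.float64)
    n = len(f)
    mask = np.zeros(n, dtype=bool)
    if n < 2 * half_q + 1:
        return mask
    core = slice(half_q, n - half_q)
    ok = np.ones(n - 2 * half_q, dtype=bool)
    center = f[core]
    for j in range(1, half_q + 1):
        fwd = center - f[half_q + j : n - half_q + j]
        bwd = center - f[half_q - j : n - half_q - j]
        ok &= (fwd * bwd) > 0
        if not ok.any():
            break
    mask[core] = ok
    return mask


def find_extremes(
    f: FilteredSignal, plan: list[WindowPlan], half_q: int | None = None
) -> ExtremeSet:
    """Extreme points per window (window extended by its context).

    The dominance radius equals half a QRS width; by construction the
    side context carries the same value, so it is the default.
    """
    if not plan:
        return ExtremeSet(())
    if half_q is None:
        half_q = plan[0].context
    if half_q < 1:
        raise ValueError("half_q must be >= 1")
    mask = extreme_mask(f.values, half_q)
    out = []
    n = len(f.values)
    for w in plan:
        lo = max(w.origin - w.context, 0)
        hi = min(w.origin + w.length + w.context, n)
        idx = np.nonzero(mask[lo:hi])[0] + lo
        out.append(idx.astype(np.int64))
    return ExtremeSet(tuple(out))
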