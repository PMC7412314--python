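"""Adaptive threshold with proportional-derivative control.

The threshold at the first point of each analysis window follows

    TH[w] = TH[w-1] - a*(TH[w-1] - TH_min) - b*(TH[w-1] - TH[w-2])

so it relaxes geometrically toward the floor TH_min between beats (the
proportional term) while the derivative term damps abrupt jumps.  The
per-sample threshold inside a window is the linear interpolation between
the window's first-point threshold and the next window's.  An extreme
point becomes a QRS candidate when the feature signal within a small
search radius around it exceeds M times its interpolated threshold; a
detection resets the window threshold to the candidate's feature value.

Defaults: a = 0.5, b = 0.1, TH_min = 0.15, M = 1.5, search radius 15
samples, refractory interval one window (260 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nonlinear import FeatureSignal

__all__ = [
    "PdParams",
    "ThresholdState",
    "CandidateDecision",
    "init_state",
    "advance_threshold",
    "point_threshold",
    "screen_window",
    "register_detection",
]


@dataclass(frozen=True)
class PdParams:
    a: float = 0.5
    b: float = 0.1
    th_min: float = 0.15
    m_factor: float = 1.5
    search_radius: int = 15
    refractory_samples: int = 93
    init_scale: float = 0.5
    init_seconds: float = 2.0

    def __post_init__(self):
        if not 0 < self.a < 1:
            raise ValueError("a must be in (0, 1)")
        if not 0 <= self.b < 1:
            raise ValueError("b must be in [0, 1)")
        if not self.th_min > 0:
            raise ValueError("th_min must be positive")
        if self.m_factor < 1:
            raise ValueError("m_factor must be >= 1")


@dataclass(frozen=True)
class ThresholdState:
    """First-point thresholds of three consecutive windows.

    th_prev = TH[w-1], th_cur = TH[w] (the window about to be screened),
    th_next = TH[w+1].
    """

    th_prev: float
    th_cur: float
    th_next: float


@dataclass(frozen=True)
class CandidateDecision:
    detected: bool
    peak_index: int | None = None
    peak_feature: float = 0.0


def _pd_step(th: float, th_older: float, params: PdParams) -> float:
    return th - params.a * (th - params.th_min) - params.b * (th - th_older)


def init_state(s: FeatureSignal, params: PdParams, fs: float) -> ThresholdState:
    """Start-up rule: half the feature maximum over the first two seconds.

    Chosen so the first real beat (whose feature sits near that maximum)
    still clears M times the threshold while start-up noise does not.
    Falls back to the floor for an all-zero signal.
    """
    if len(s.values) == 0:
        raise ValueError("feature signal is empty")
    head = s.values[: max(1, int(round(params.init_seconds * fs)))]
    th0 = max(params.th_min, params.init_scale * float(np.max(head)))
    return ThresholdState(th0, th0, _pd_step(th0, th0, params))


def advance_threshold(state: ThresholdState, params: PdParams) -> ThresholdState:
    """Move to the next window: derive TH[w+2], then shift roles."""
    new_next = _pd_step(state.th_next, state.th_prev, params)
    return ThresholdState(state.th_cur, state.th_next, new_next)


def point_threshold(
    state: ThresholdState, offset: int, window_samples: int
) -> float:
    """Linear interpolation of the threshold at a window-relative offset."""
    frac = offset / window_samples
    return state.th_cur - (state.th_cur - state.th_next) * frac


def screen_window(
    extremes: np.ndarray,
    s: FeatureSignal,
    state: ThresholdState,
    params: PdParams,
    window_origin: int = 0,
    window_samples: int = 93,
) -> CandidateDecision:
    """Screen one window's extreme points against the running threshold.

    An extreme qualifies when the feature maximum within
    ``search_radius`` samples of it exceeds ``m_factor`` times its
    interpolated threshold (the search absorbs the small alignment lag
    between the filtered signal and the accumulated feature).  The
    qualifying extreme with the largest such maximum wins.
    """
    vals = s.values
    n = len(vals)
    best_idx: int | None = None
    best_feat = 0.0
    best_at_e = -1.0
    for e in np.asarray(extremes, dtype=np.int64):
        lo = max(int(e) - params.search_radius, 0)
        hi = min(int(e) + params.search_radius + 1, n)
        if lo >= hi:
            continue
        local = float(np.max(vals[lo:hi]))
        offset = min(max(int(e) - window_origin, 0), window_samples)
        th = point_threshold(state, offset, window_samples)
        if local <= params.m_factor * th:
            continue
        # several extremes of one QRS share the same search-window
        # maximum; break ties by the feature at the extreme itself so
        # the wave's main lobe wins over its side lobes
        at_e = float(vals[e]) if 0 <= e < n else 0.0
        if local > best_feat or (local == best_feat and at_e > best_at_e):
            best_idx = int(e)
            best_feat = local
            best_at_e = at_e
    if best_idx is None:
        return CandidateDecision(False)
    return CandidateDecision(True, best_idx, best_feat)


def register_detection(
    state: ThresholdState, peak_feature: float, params: PdParams
) -> ThresholdState:
    """Accept a candidate: TH[w] <- s at the beat, re-derive TH[w+1].

    The caller still applies :func:`advance_threshold` afterwards, which
    mirrors the unconditional shift at the end of every window.
    """
    if not peak_feature > 0:
        raise ValueError("peak_feature must be positive")
    new_cur = float(peak_feature)
    new_next = _pd_step(new_cur, state.th_prev, params)
    return replace(state, th_cur=new_cur, th_next=new_next)
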