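"""Beat-matching and detection metrics (Se, P+, Acc).

Detections are matched one-to-one against reference beats by a greedy
nearest-neighbour sweep in ascending time within a tolerance window.
Metrics follow the standard definitions

    Se  = TP / (TP + FN)
    P+  = TP / (TP + FP)
    Acc = TP / (TP + FP + FN)

reported as percentages rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .signal_io import BeatAnnotations

__all__ = [
    "MatchResult",
    "Metrics",
    "match_beats",
    "compute_metrics",
    "apply_exclusions",
]


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class Metrics:
    """Percentages rounded to 2 decimals; None where the ratio is 0/0."""

    se: float | None
    ppv: float | None
    acc: float | None
    se_raw: float = float("nan")
    ppv_raw: float = float("nan")
    acc_raw: float = float("nan")


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def apply_exclusions(
    indices: np.ndarray, exclusions: list[tuple[int, int]]
) -> np.ndarray:
    """Drop indices inside any half-open [start, stop) exclusion interval."""
    keep = np.ones(len(indices), dtype=bool)
    for start, stop in exclusions:
        keep &= ~((indices >= start) & (indices < stop))
    return indices[keep]


def match_beats(
    detected: BeatAnnotations,
    reference: BeatAnnotations,
    tolerance: int,
    exclusions: list[tuple[int, int]] | None = None,
) -> MatchResult:
    """Greedy one-to-one matching in ascending time.

    Each reference beat takes the nearest still-unmatched detection
    within ``tolerance`` samples (earlier detection on a distance tie).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    det = np.asarray(detected.indices, dtype=np.int64)
    ref = np.asarray(reference.indices, dtype=np.int64)
    if exclusions:
        det = apply_exclusions(det, exclusions)
        ref = apply_exclusions(ref, exclusions)
    used = np.zeros(len(det), dtype=bool)
    pairs: list[tuple[int, int]] = []
    j = 0
    for r in ref:
        # candidates within tolerance of r, not yet used
        while j < len(det) and det[j] < r - tolerance:
            j += 1
        best = -1
        best_dist = tolerance + 1
        k = j
        while k < len(det) and det[k] <= r + tolerance:
            if not used[k]:
                dist = abs(int(det[k]) - int(r))
                if dist < best_dist:
                    best_dist = dist
                    best = k
            k += 1
        if best >= 0:
            used[best] = True
            pairs.append((int(det[best]), int(r)))
    tp = len(pairs)
    return MatchResult(tp, int(len(det) - tp), int(len(ref) - tp),
                       tuple(pairs))


def compute_metrics(m: MatchResult) -> Metrics:
    """Se, P+ and Acc from TP/FP/FN counts."""
    def ratio(num: int, den: int) -> tuple[float | None, float]:
        if den == 0:
            return None, float("nan")
        raw = 100.0 * num / den
        return _round2(raw), raw

    se, se_raw = ratio(m.tp, m.tp + m.fn)
    ppv, ppv_raw = ratio(m.tp, m.tp + m.fp)
    acc, acc_raw = ratio(m.tp, m.tp + m.fp + m.fn)
    return Metrics(se, ppv, acc, se_raw, ppv_raw, acc_raw)
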