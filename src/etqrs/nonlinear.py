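"""Nonlinear energy transforms and moving accumulation.

The primary transform maps the differenced signal through
``e(n) = |d(n)| * exp(-|d(n)|)``, which removes polarity and compresses
large slopes so that small/wide QRS complexes survive a shared
threshold.  A first-order approximation ``|d| - d^2`` is provided for
fixed-point/hardware parity, as are the classic absolute-value and
squared alternatives used for comparison.

All four feed a centered moving sum over one nominal QRS duration
(120 ms), producing the feature signal s(n) that the detector
thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import DifferencedSignal

__all__ = [
    "TransformParams",
    "TransformedSignal",
    "FeatureSignal",
    "exponential_transform",
    "accumulate",
    "abs_accumulate",
    "square_accumulate",
]

DEFAULT_QRS_DURATION_MS = 120.0


def qrs_width_samples(fs: float, duration_ms: float = DEFAULT_QRS_DURATION_MS) -> int:
    """q = floor(duration * fs); 43 samples at 360 Hz."""
    return int(math.floor(duration_ms / 1000.0 * fs))


@dataclass(frozen=True)
class TransformParams:
    q: int
    mode: str = "exact"
    clamp_negative: bool = True
    half_q: int = field(init=False)

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.mode not in ("exact", "taylor"):
            raise ValueError(f"unknown transform mode {self.mode!r}")
        object.__setattr__(self, "half_q", self.q // 2)

    @classmethod
    def for_fs(cls, fs: float, mode: str = "exact",
               duration_ms: float = DEFAULT_QRS_DURATION_MS,
               clamp_negative: bool = True) -> "TransformParams":
        return cls(qrs_width_samples(fs, duration_ms), mode, clamp_negative)


@dataclass(frozen=True)
class TransformedSignal:
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureSignal:
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def _et_values(d: np.ndarray, params: TransformParams) -> np.ndarray:
    a = np.abs(d)
    if params.mode == "exact":
        return a * np.exp(-a)
    out = a - d * d
    if params.clamp_negative:
        np.maximum(out, 0.0, out=out)
    return out


def exponential_transform(
    d: DifferencedSignal, params: TransformParams
) -> TransformedSignal:
    """Polarity-free energy: |d|e^{-|d|} (exact) or |d| - d^2 (taylor)."""
    return TransformedSignal(_et_values(np.asarray(d.values, float), params))


def _box_sum(e: np.ndarray, half_q: int) -> np.ndarray:
    # centered window of 2*half_q + 1 points, zero-padded at the edges
    kernel = np.ones(2 * half_q + 1)
    return np.convolve(e, kernel, mode="same")


def accumulate(e: TransformedSignal, params: TransformParams) -> FeatureSignal:
    """s(n) = sum of e over [n - half_q, n + half_q], zero-padded."""
    return FeatureSignal(_box_sum(np.asarray(e.values, float), params.half_q))


def abs_accumulate(d: DifferencedSignal, params: TransformParams) -> FeatureSignal:
    """Comparison transform: moving sum of |d|."""
    return FeatureSignal(_box_sum(np.abs(np.asarray(d.values, float)),
                                  params.half_q))


def square_accumulate(d: DifferencedSignal, params: TransformParams) -> FeatureSignal:
    """Comparison transform: moving sum of d^2."""
    vals = np.asarray(d.values, float)
    return FeatureSignal(_box_sum(vals * vals, params.half_q))
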