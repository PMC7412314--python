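"""Band-pass filtering and first-order forward differencing.

The front end is a 41-tap linear-phase FIR band-pass (5-15 Hz, Hamming
window) followed by the forward difference d(n) = f(n+1) - f(n), which
sharpens QRS slopes and suppresses the slower P and T waves.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .signal_io import EcgRecord

__all__ = [
    "FilterSpec",
    "FilteredSignal",
    "DifferencedSignal",
    "design_bandpass",
    "apply_filter",
    "differentiate",
]

DEFAULT_TAPS = 41
DEFAULT_LOW_HZ = 5.0
DEFAULT_HIGH_HZ = 15.0


@dataclass(frozen=True)
class FilterSpec:
    fs: float
    taps: int = DEFAULT_TAPS
    low_hz: float = DEFAULT_LOW_HZ
    high_hz: float = DEFAULT_HIGH_HZ
    window_kind: str = "hamming"

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz < self.fs / 2:
            raise ValueError(
                f"band edges must satisfy 0 < low < high < fs/2, got "
                f"({self.low_hz}, {self.high_hz}) at fs={self.fs}"
            )
        if self.taps < 3 or self.taps % 2 == 0:
            raise ValueError("taps must be odd and >= 3 for a type-I FIR")

    @property
    def group_delay(self) -> int:
        return (self.taps - 1) // 2


@dataclass(frozen=True)
class FilteredSignal:
    values: np.ndarray
    group_delay: int
    fs: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DifferencedSignal:
    values: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.values)


@lru_cache(maxsize=8)
def _cached_design(fs: float, taps: int, low: float, high: float,
                   window: str) -> tuple[float, ...]:
    coeffs = sps.firwin(
        taps, [low, high], window=window, pass_zero=False, fs=fs
    )
    # With so few taps the transition band is ~3.3*fs/taps wide, so the
    # raw windowed-sinc design leaks heavily at DC (gain ~0.8 here) and
    # would pass baseline wander straight through.  Subtracting the
    # coefficient mean pins the DC gain to exactly zero while leaving
    # symmetry (hence the integer group delay) and the passband intact.
    coeffs = coeffs - coeffs.mean()
    return tuple(coeffs)


def design_bandpass(spec: FilterSpec) -> np.ndarray:
    """Windowed-sinc band-pass coefficients; symmetric, hence linear phase.

    The design is constrained to zero DC gain so sub-hertz baseline
    wander is rejected even at this short filter length.
    """
    return np.asarray(
        _cached_design(
            spec.fs, spec.taps, spec.low_hz, spec.high_hz, spec.window_kind
        )
    )


def apply_filter(record: EcgRecord, coeffs: np.ndarray) -> FilteredSignal:
    """Causal zero-padded convolution truncated to the input length.

    The (taps-1)/2-sample group delay is recorded on the output but not
    compensated here; the pipeline subtracts it when reporting beats.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if len(record.samples) < len(coeffs):
        raise ValueError(
            f"record length {len(record.samples)} shorter than filter "
            f"({len(coeffs)} taps)"
        )
    out = sps.lfilter(coeffs, [1.0], record.samples)
    return FilteredSignal(out, (len(coeffs) - 1) // 2, record.fs)


def differentiate(f: FilteredSignal) -> DifferencedSignal:
    """Forward difference: d(n) = f(n+1) - f(n), length len(f) - 1."""
    if len(f.values) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return DifferencedSignal(np.diff(f.values), f.fs)
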