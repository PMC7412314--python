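"""End-to-end streaming QRS detection.

Five stages per analysis window: band-pass + difference, exponential
transform + accumulation, extreme-point search, PD-threshold screening,
tall-T rejection.  The record is consumed in chunks (default 2^14
samples); in ``persist`` mode the filter state, threshold state and RR
tracker carry across chunk boundaries, making chunked and full-record
runs bit-identical.  ``reset`` mode re-initializes everything per chunk,
emulating independent analysis units.

Reported beat positions are in raw-signal coordinates: the 20-sample
filter group delay is subtracted, and optionally the position is refined
to the raw amplitude maximum nearby.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import signal as sps

from . import nonlinear, pd_threshold, peak_detect, preprocess, twave_reject
from .nonlinear import FeatureSignal, TransformParams
from .pd_threshold import PdParams, ThresholdState
from .peak_detect import extreme_mask
from .preprocess import FilterSpec
from .signal_io import EcgRecord
from .twave_reject import Beat, RrTracker

__all__ = ["DetectorConfig", "DetectionResult", "detect",
           "compensate_position"]


@dataclass(frozen=True)
class DetectorConfig:
    # filter
    taps: int = 41
    low_hz: float = 5.0
    high_hz: float = 15.0
    # nonlinear transform
    mode: str = "exact"
    qrs_duration_ms: float = 120.0
    clamp_negative: bool = True
    # windows & threshold
    window_ms: float = 260.0
    a: float = 0.5
    b: float = 0.1
    th_min: float = 0.15
    m_factor: float = 1.5
    search_radius: int = 15
    init_scale: float = 0.5
    init_seconds: float = 2.0
    # tall-T rejection
    k_divisor: float = 3.0
    tall_t_enabled: bool = True
    tall_t_literal: bool = False
    # chunking & reporting
    chunk_samples: int = 1 << 14
    chunk_state: str = "persist"
    report_compensation: str = "group_delay_only"
    refine_ms: float = 36.0

    _KEYMAP = {
        "filter.taps": ("taps", int),
        "filter.low_hz": ("low_hz", float),
        "filter.high_hz": ("high_hz", float),
        "transform.mode": ("mode", str),
        "transform.qrs_duration_ms": ("qrs_duration_ms", float),
        "transform.clamp_negative": ("clamp_negative", None),
        "detector.window_ms": ("window_ms", float),
        "detector.a": ("a", float),
        "detector.b": ("b", float),
        "detector.th_min": ("th_min", float),
        "detector.m_factor": ("m_factor", float),
        "detector.search_radius": ("search_radius", int),
        "detector.init_scale": ("init_scale", float),
        "detector.init_seconds": ("init_seconds", float),
        "detector.k_divisor": ("k_divisor", float),
        "detector.tall_t_enabled": ("tall_t_enabled", None),
        "detector.tall_t_literal": ("tall_t_literal", None),
        "pipeline.chunk_samples": ("chunk_samples", int),
        "pipeline.chunk_state": ("chunk_state", str),
        "pipeline.report_compensation": ("report_compensation", str),
        "pipeline.refine_ms": ("refine_ms", float),
    }

    def __post_init__(self):
        if self.chunk_state not in ("persist", "reset"):
            raise ValueError("chunk_state must be 'persist' or 'reset'")
        if self.report_compensation not in ("group_delay_only",
                                            "refine_to_raw_max"):
            raise ValueError("unknown report_compensation mode")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DetectorConfig":
        kwargs = {}
        for key, raw in mapping.items():
            if key not in cls._KEYMAP:
                raise KeyError(f"unknown config key {key!r}")
            name, conv = cls._KEYMAP[key]
            if conv is None:  # boolean
                val = str(raw).strip().lower() in ("1", "true", "yes", "on")
            else:
                val = conv(raw)
            kwargs[name] = val
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "DetectorConfig":
        """Flat ``key = value`` text config."""
        mapping = {}
        with open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                key, val = (part.strip() for part in line.split("=", 1))
                mapping[key] = val
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class _Derived:
    """All per-fs sample-count parameters, derived from their ms values."""

    fs: float
    window_samples: int
    q: int
    half_q: int
    group_delay: int
    refine_samples: int

    @classmethod
    def build(cls, fs: float, config: DetectorConfig) -> "_Derived":
        return cls(
            fs=fs,
            window_samples=peak_detect.window_samples_for_fs(
                fs, config.window_ms),
            q=nonlinear.qrs_width_samples(fs, config.qrs_duration_ms),
            half_q=nonlinear.qrs_width_samples(fs, config.qrs_duration_ms) // 2,
            group_delay=(config.taps - 1) // 2,
            refine_samples=int(round(config.refine_ms / 1000.0 * fs)),
        )


@dataclass(frozen=True)
class DetectionResult:
    beat_indices: np.ndarray  # raw-signal coordinates, strictly ascending
    beat_features: np.ndarray
    threshold_trace: tuple[tuple[int, float], ...]  # (window origin, TH)
    counters: dict
    fs: float

    def __len__(self) -> int:
        return len(self.beat_indices)


@dataclass
class _BeatRec:
    index: int  # filtered-signal coordinates
    feature: float
    window: int
    pre_state: ThresholdState


class _StreamingDetector:
    """Incremental five-stage detector over a growing sample stream."""

    def __init__(self, fs: float, config: DetectorConfig):
        self.cfg = config
        self.fs = fs
        self.der = _Derived.build(fs, config)
        spec = FilterSpec(fs, config.taps, config.low_hz, config.high_hz)
        self.coeffs = preprocess.design_bandpass(spec)
        self.tparams = TransformParams(self.der.q, config.mode,
                                       config.clamp_negative)
        self.pd = PdParams(config.a, config.b, config.th_min,
                           config.m_factor, config.search_radius,
                           self.der.window_samples,
                           config.init_scale, config.init_seconds)
        self.zi = np.zeros(config.taps - 1)
        self.f = np.empty(0)
        self.e = np.empty(0)
        self.cs = np.zeros(1)  # cumulative sum of e, with leading 0
        self.mask = np.empty(0, dtype=bool)
        self.state: ThresholdState | None = None
        self.next_window = 0
        self.beats: list[_BeatRec] = []
        self.trace: list[tuple[int, float]] = []
        self.counters = {
            "windows": 0, "extremes": 0, "candidates": 0,
            "refractory_replaced": 0, "refractory_dropped": 0,
            "tall_t_rejected": 0,
        }
        self.finalized = False

    # -- stream maintenance -------------------------------------------------

    def feed(self, chunk: np.ndarray) -> None:
        if self.finalized:
            raise RuntimeError("detector already finalized")
        chunk = np.asarray(chunk, dtype=np.float64)
        if len(chunk) == 0:
            return
        out, self.zi = sps.lfilter(self.coeffs, [1.0], chunk, zi=self.zi)
        self.f = np.concatenate([self.f, out])
        self._extend_derived()
        self._process_ready_windows(final=False)

    def finalize(self) -> None:
        if not self.finalized:
            self.finalized = True
            self._extend_derived()
            self._process_ready_windows(final=True)

    def _extend_derived(self) -> None:
        n_f = len(self.f)
        if n_f >= 2:
            new_e_hi = n_f - 1
            if new_e_hi > len(self.e):
                d_new = np.diff(self.f[len(self.e):])
                e_new = nonlinear._et_values(d_new, self.tparams)
                self.e = np.concatenate([self.e, e_new])
                self.cs = np.concatenate([[0.0], np.cumsum(self.e)])
        hq = self.der.half_q
        mask_hi = max(n_f - hq, len(self.mask))
        if mask_hi > len(self.mask):
            start = len(self.mask)
            seg_lo = max(start - hq, 0)
            seg = extreme_mask(self.f[seg_lo:], hq)
            grown = np.zeros(mask_hi, dtype=bool)
            grown[: len(self.mask)] = self.mask
            grown[start:] = seg[start - seg_lo : mask_hi - seg_lo]
            self.mask = grown

    def _s_segment(self, lo: int, hi: int) -> np.ndarray:
        """s(lo:hi) from the cumulative sum, zero-padded at the edges."""
        hq = self.der.half_q
        n_e = len(self.e)
        idx = np.arange(lo, hi)
        upper = np.clip(idx + hq + 1, 0, n_e)
        lower = np.clip(idx - hq, 0, n_e)
        return self.cs[upper] - self.cs[lower]

    # -- window processing --------------------------------------------------

    def _window_need(self, origin: int, length: int) -> int:
        der = self.der
        need = origin + length + der.half_q * 2 + self.pd.search_radius + 2
        if self.state is None:
            init_need = int(round(self.pd.init_seconds * self.fs)) + \
                der.half_q + 2
            need = max(need, init_need)
        return need

    def _process_ready_windows(self, final: bool) -> None:
        W = self.der.window_samples
        n_f = len(self.f)
        while True:
            origin = self.next_window * W
            if final:
                if origin >= n_f:
                    break
                length = min(W, n_f - origin)
                # skip a final sliver handled entirely by earlier context
                if length < 1:
                    break
            else:
                length = W
                if n_f < self._window_need(origin, length) or \
                        origin + length > n_f:
                    break
            self._process_window(self.next_window, origin, length)
            self.next_window += 1

    def _process_window(self, w: int, origin: int, length: int) -> None:
        der = self.der
        hq = der.half_q
        lo = max(origin - hq, 0)
        hi = min(origin + length + hq, len(self.mask))
        extremes = np.nonzero(self.mask[lo:hi])[0] + lo

        if self.state is None:
            head = self._s_segment(
                0, max(1, int(round(self.pd.init_seconds * self.fs))))
            self.state = pd_threshold.init_state(
                FeatureSignal(head), self.pd, self.fs)

        self.counters["windows"] += 1
        self.counters["extremes"] += len(extremes)
        self.trace.append((origin, self.state.th_cur))

        seg_lo = max(lo - self.pd.search_radius, 0)
        seg_hi = hi + self.pd.search_radius
        seg = self._s_segment(seg_lo, seg_hi)
        decision = pd_threshold.screen_window(
            extremes - seg_lo,
            FeatureSignal(seg),
            self.state,
            self.pd,
            window_origin=origin - seg_lo,
            window_samples=der.window_samples,
        )
        if decision.detected:
            self.counters["candidates"] += 1
            self._accept(decision.peak_index + seg_lo,
                         decision.peak_feature, w)
        else:
            self.state = pd_threshold.advance_threshold(self.state, self.pd)

    # -- candidate bookkeeping ---------------------------------------------

    def _tracker(self) -> RrTracker:
        # equivalent to folding every kept interval through update_mean_rr
        idx = [b.index for b in self.beats]
        if len(idx) < 2:
            return RrTracker(k_divisor=self.cfg.k_divisor)
        intervals = np.diff(idx)
        return RrTracker(float(np.mean(intervals)), len(intervals),
                         self.cfg.k_divisor)

    def _accept(self, index: int, feature: float, w: int) -> None:
        last = self.beats[-1] if self.beats else None
        if last is not None and abs(index - last.index) < \
                self.pd.refractory_samples:
            if index != last.index and feature > last.feature:
                # new candidate wins: roll back the loser's threshold
                # update and replay the windows since as empty
                st = last.pre_state
                for _ in range(w - last.window):
                    st = pd_threshold.advance_threshold(st, self.pd)
                self.state = st
                self.beats.pop()
                self.counters["refractory_replaced"] += 1
            else:
                self.counters["refractory_dropped"] += 1
                self.state = pd_threshold.advance_threshold(self.state,
                                                            self.pd)
                return

        pre_state = self.state
        self.state = pd_threshold.register_detection(self.state, feature,
                                                     self.pd)
        self.state = pd_threshold.advance_threshold(self.state, self.pd)
        new = _BeatRec(index, feature, w, pre_state)

        if self.cfg.tall_t_enabled and self.beats:
            prev = self.beats[-1]
            tracker = self._tracker()
            kept = twave_reject.resolve_tall_t(
                Beat(prev.index, prev.feature),
                Beat(new.index, new.feature),
                tracker,
                literal=self.cfg.tall_t_literal,
            )
            if len(kept) == 1:
                self.counters["tall_t_rejected"] += 1
                if kept[0].index == new.index:
                    self.beats.pop()
                    self.beats.append(new)
                # else: new candidate rejected as a T wave
                return
        self.beats.append(new)


def _iter_chunks(samples: np.ndarray, size: int) -> Iterable[np.ndarray]:
    for start in range(0, len(samples), size):
        yield samples[start : start + size]


def compensate_position(
    filtered_index: int,
    config: DetectorConfig,
    fs: float,
    raw_samples: np.ndarray | None = None,
) -> int:
    """Map a filtered-signal index back to raw-signal coordinates.

    Subtracts the FIR group delay; in ``refine_to_raw_max`` mode the
    position additionally snaps to the largest absolute raw amplitude
    within the refine radius.
    """
    der = _Derived.build(fs, config)
    raw = filtered_index - der.group_delay
    if raw < 0:
        warnings.warn("compensated beat index underflowed; clipped to 0")
        raw = 0
    if config.report_compensation == "refine_to_raw_max" and \
            raw_samples is not None:
        # hill-climb to the dominant raw deflection; iterate so a peak
        # just beyond the first search window is still reached
        for _ in range(5):
            lo = max(raw - der.refine_samples, 0)
            hi = min(raw + der.refine_samples + 1, len(raw_samples))
            if lo >= hi:
                break
            seg = raw_samples[lo:hi]
            new_raw = lo + int(np.argmax(np.abs(seg - np.mean(seg))))
            if new_raw == raw:
                break
            raw = new_raw
    return raw


def _run_stream(samples: np.ndarray, fs: float,
                config: DetectorConfig) -> _StreamingDetector:
    det = _StreamingDetector(fs, config)
    for chunk in _iter_chunks(samples, config.chunk_samples):
        det.feed(chunk)
    det.finalize()
    return det


def detect(record: EcgRecord, config: DetectorConfig | None = None
           ) -> DetectionResult:
    """Run the full five-stage detector over a record."""
    if config is None:
        config = DetectorConfig()
    der = _Derived.build(record.fs, config)
    if len(record.samples) <= der.window_samples:
        raise ValueError(
            f"record length {len(record.samples)} does not cover one "
            f"analysis window ({der.window_samples} samples)"
        )
    if config.chunk_samples <= der.window_samples + 2 * der.half_q:
        raise ValueError("chunk_samples too small for one window + context")

    if config.chunk_state == "persist":
        det = _run_stream(record.samples, record.fs, config)
        raw_beats = [(b.index, b.feature) for b in det.beats]
        trace = list(det.trace)
        counters = dict(det.counters)
    else:
        raw_beats, trace, counters = _run_reset_chunks(record, config, der)

    return _assemble(record, config, der, raw_beats, trace, counters)


def _run_reset_chunks(record: EcgRecord, config: DetectorConfig,
                      der: _Derived):
    """Independent analysis units: state re-initialized per chunk."""
    n = len(record.samples)
    size = config.chunk_samples
    bounds = list(range(0, n, size)) + [n]
    # fold a final sliver that cannot host a window into the previous chunk
    if len(bounds) > 2 and bounds[-1] - bounds[-2] <= der.window_samples:
        bounds.pop(-2)
    raw_beats: list[tuple[int, float]] = []
    trace: list[tuple[int, float]] = []
    counters: dict = {}
    for start, stop in zip(bounds[:-1], bounds[1:]):
        det = _StreamingDetector(record.fs, config)
        det.feed(record.samples[start:stop])
        det.finalize()
        for b in det.beats:
            # suppress per-chunk filter transients except in the first
            # chunk, where the global rule applies anyway
            if start > 0 and b.index < config.taps - 1:
                continue
            raw_beats.append((b.index + start, b.feature))
        trace.extend((origin + start, th) for origin, th in det.trace)
        for key, val in det.counters.items():
            counters[key] = counters.get(key, 0) + val
    # enforce the refractory interval across seams
    merged: list[tuple[int, float]] = []
    for idx, feat in sorted(raw_beats):
        if merged and idx - merged[-1][0] < der.window_samples:
            if feat > merged[-1][1]:
                merged[-1] = (idx, feat)
        else:
            merged.append((idx, feat))
    return merged, trace, counters


def _assemble(record, config, der, raw_beats, trace, counters):
    indices = []
    features = []
    for idx, feat in raw_beats:
        raw = compensate_position(idx, config, record.fs, record.samples)
        if raw < config.taps - 1:  # initial filter transient
            continue
        indices.append(raw)
        features.append(feat)
    idx_arr = np.asarray(indices, dtype=np.int64)
    feat_arr = np.asarray(features, dtype=np.float64)
    # refinement can reorder or collide neighbouring beats; keep the
    # stronger of any colliding pair
    order = np.argsort(idx_arr, kind="stable")
    idx_arr, feat_arr = idx_arr[order], feat_arr[order]
    keep_idx: list[int] = []
    keep_feat: list[float] = []
    for i, f in zip(idx_arr, feat_arr):
        if keep_idx and i - keep_idx[-1] < der.window_samples:
            if f > keep_feat[-1]:
                keep_idx[-1], keep_feat[-1] = int(i), float(f)
        else:
            keep_idx.append(int(i))
            keep_feat.append(float(f))
    return DetectionResult(
        np.asarray(keep_idx, dtype=np.int64),
        np.asarray(keep_feat, dtype=np.float64),
        tuple(trace),
        counters,
        record.fs,
    )
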