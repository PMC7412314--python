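"""Seeded synthetic annotated-ECG generator.

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) placed on a
quasi-periodic RR grid drawn from a log-normal distribution.  Optional
ingredients exercise specific detector behaviours: wide low-amplitude
PVC-like beats, tall T waves, sudden rate changes, baseline wander,
powerline interference and white noise at a target SNR.  The template
parameters are fixture constants — convenient shapes for testing, not
physiological claims.  Ground truth lists the exact R-center sample of
every beat placed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import BeatAnnotations, EcgRecord

__all__ = ["Wave", "SynthConfig", "GroundTruth", "generate", "preset",
           "PRESET_NAMES"]


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: amplitude (mV), width = sigma (ms), offset from R (ms)."""

    amp_mv: float
    width_ms: float
    offset_ms: float


DEFAULT_WAVES: dict[str, Wave] = {
    "P": Wave(0.15, 25.0, -160.0),
    "Q": Wave(-0.10, 10.0, -25.0),
    "R": Wave(1.00, 12.0, 0.0),
    "S": Wave(-0.25, 10.0, 25.0),
    "T": Wave(0.30, 70.0, 300.0),
}

# PVC-like replacement for the R wave: low, wide (~100 ms at half
# maximum, i.e. twice the normal QRS), no P wave.
PVC_WAVE = Wave(0.45, 25.0, 0.0)
# Tall-T beats: narrow enough to retain band-pass energy, >= 0.8 x R.
TALL_T_WAVE = Wave(0.85, 35.0, 300.0)


@dataclass(frozen=True)
class SynthConfig:
    duration_s: float = 60.0
    fs: float = 360.0
    mean_hr_bpm: float = 72.0
    rr_cv: float = 0.05
    rr_jump: tuple[tuple[float, float], ...] = ()  # (time_s, rr factor)
    wave_set: dict[str, Wave] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    r_amp_cv: float = 0.05
    pvc_rate: float = 0.0
    tall_t_rate: float = 0.0
    noise_snr_db: float | None = None
    baseline: tuple[float, float] | None = None  # (amp mV, freq Hz < 0.5)
    powerline: tuple[float, float] | None = None  # (amp mV, 50 or 60 Hz)
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0 or self.mean_hr_bpm <= 0:
            raise ValueError("duration, fs and heart rate must be positive")
        for rate in (self.pvc_rate, self.tall_t_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.powerline is not None and self.fs <= 2 * self.powerline[1]:
            raise ValueError("fs must exceed twice the powerline frequency")
        for w in self.wave_set.values():
            if w.width_ms <= 0:
                raise ValueError("wave widths must be positive")


@dataclass(frozen=True)
class GroundTruth:
    annotations: BeatAnnotations
    beat_types: tuple[str, ...]


def _rr_samples(rng: np.random.Generator, cfg: SynthConfig) -> "RrSampler":
    return RrSampler(rng, cfg)


class RrSampler:
    """Log-normal RR sampler with optional sudden rate changes."""

    def __init__(self, rng: np.random.Generator, cfg: SynthConfig):
        self.rng = rng
        self.cfg = cfg
        self.jumps = sorted(cfg.rr_jump)

    def draw(self, t_s: float) -> float:
        mean = 60.0 / self.cfg.mean_hr_bpm
        for jump_t, factor in self.jumps:
            if t_s >= jump_t:
                mean = 60.0 / self.cfg.mean_hr_bpm * factor
        cv = self.cfg.rr_cv
        if cv <= 0:
            return mean
        sigma2 = math.log(1.0 + cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        return float(self.rng.lognormal(mu, math.sqrt(sigma2)))


def generate(config: SynthConfig) -> tuple[EcgRecord, GroundTruth]:
    """Render the configured record; identical seed, identical output."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    clean = np.zeros(n)

    sampler = _rr_samples(rng, config)
    # leave room for the leading P and the trailing T wave
    lead_margin = 0.25
    tail_margin = 0.45
    beat_times: list[float] = []
    beat_types: list[str] = []
    cur = 0.5
    while cur < config.duration_s - tail_margin:
        beat_times.append(cur)
        u = rng.uniform()
        if u < config.pvc_rate:
            beat_types.append("pvc")
        elif u < config.pvc_rate + config.tall_t_rate:
            beat_types.append("tall_t")
        else:
            beat_types.append("normal")
        cur += sampler.draw(cur)

    for bt, kind in zip(beat_times, beat_types):
        r_scale = 1.0
        if config.r_amp_cv > 0:
            r_scale = max(0.2, 1.0 + config.r_amp_cv * rng.standard_normal())
        for name, wave in _beat_waves(config, kind):
            amp = wave.amp_mv * (r_scale if name in ("R", "PVC") else 1.0)
            center = bt + wave.offset_ms / 1000.0
            sigma = wave.width_ms / 1000.0
            lo = max(0, int((center - 5 * sigma) * fs))
            hi = min(n, int((center + 5 * sigma) * fs) + 1)
            if lo >= hi:
                continue
            tt = t[lo:hi] - center
            clean[lo:hi] += amp * np.exp(-0.5 * (tt / sigma) ** 2)

    samples = clean.copy()
    if config.baseline is not None:
        amp, freq = config.baseline
        samples += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    if config.powerline is not None:
        amp, freq = config.powerline
        samples += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    if config.noise_snr_db is not None and math.isfinite(config.noise_snr_db):
        sig_power = float(np.mean(clean**2))
        noise_power = sig_power / (10.0 ** (config.noise_snr_db / 10.0))
        samples += rng.normal(0.0, math.sqrt(noise_power), size=n)

    r_samples = np.asarray([int(round(bt * fs)) for bt in beat_times],
                           dtype=np.int64)
    record = EcgRecord(samples, fs, record_id=f"synth-{config.seed}")
    truth = GroundTruth(BeatAnnotations(r_samples, tuple(beat_types)),
                        tuple(beat_types))
    return record, truth


def _beat_waves(config: SynthConfig, kind: str):
    waves = config.wave_set
    if kind == "pvc":
        yield "PVC", PVC_WAVE
        if "T" in waves:
            yield "T", waves["T"]
        return
    for name, wave in waves.items():
        if kind == "tall_t" and name == "T":
            yield "T", TALL_T_WAVE
        else:
            yield name, wave


PRESETS: dict[str, SynthConfig] = {
    "clean": SynthConfig(rr_cv=0.03, r_amp_cv=0.0),
    "pvc": SynthConfig(pvc_rate=0.2),
    # slow rate keeps the R->T gap between the refractory interval and
    # the mean-RR/K cutoff, so the T candidates reach the rejection stage
    "tall_t": SynthConfig(tall_t_rate=0.3, mean_hr_bpm=40.0),
    "noisy": SynthConfig(noise_snr_db=10.0, baseline=(0.3, 0.3)),
    "rr_jump": SynthConfig(rr_jump=((20.0, 0.6), (40.0, 1.4))),
}
PRESET_NAMES = tuple(PRESETS)


def preset(name: str, **overrides) -> SynthConfig:
    """A documented fixed configuration, optionally overridden."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}"
        ) from None
    return replace(base, **overrides) if overrides else base
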