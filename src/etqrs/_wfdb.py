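"""Minimal reader/writer for the WFDB record family (.hea/.dat/.atr).

Only the subset needed for single-lead QRS work is supported: signal
formats 16 (little-endian int16) and 212 (packed 12-bit pairs), and the
MIT annotation format restricted to the annotation types that occur in
beat files.  This avoids a runtime dependency on the full ``wfdb``
package, which is not always available offline.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

# MIT annotation type codes that mark beats (QRS complexes).
BEAT_CODES = frozenset(
    {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 30, 34, 35, 38, 41}
)

CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {v: k for k, v in CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalSpec:
    file_name: str
    fmt: int
    gain: float = 200.0
    baseline: int = 0
    units: str = "mV"
    adc_zero: int = 0
    description: str = ""


@dataclass
class Header:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[SignalSpec] = field(default_factory=list)


class WfdbFormatError(ValueError):
    """Malformed or unsupported WFDB content."""


def read_header(path: str) -> Header:
    with open(path, "rt", encoding="ascii", errors="replace") as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise WfdbFormatError(f"empty header file: {path}")
    toks = lines[0].split()
    if len(toks) < 2:
        raise WfdbFormatError(f"malformed record line in {path!r}")
    name = toks[0].split("/")[0]
    try:
        n_sig = int(toks[1])
        fs = float(toks[2].split("/")[0]) if len(toks) > 2 else 250.0
        n_samples = int(toks[3]) if len(toks) > 3 else 0
    except ValueError as exc:
        raise WfdbFormatError(f"malformed record line in {path!r}") from exc
    hdr = Header(name, n_sig, fs, n_samples)
    for ln in lines[1 : 1 + n_sig]:
        hdr.signals.append(_parse_signal_line(ln))
    if len(hdr.signals) != n_sig:
        raise WfdbFormatError(
            f"{path!r}: expected {n_sig} signal lines, found {len(hdr.signals)}"
        )
    return hdr


def _parse_signal_line(line: str) -> SignalSpec:
    toks = line.split()
    if len(toks) < 2:
        raise WfdbFormatError(f"malformed signal line: {line!r}")
    file_name = toks[0]
    fmt_tok = toks[1].split("x")[0].split(":")[0].split("+")[0]
    try:
        fmt = int(fmt_tok)
    except ValueError as exc:
        raise WfdbFormatError(f"bad signal format in {line!r}") from exc
    spec = SignalSpec(file_name=file_name, fmt=fmt)
    if len(toks) > 2:
        gain_tok = toks[2]
        units = "mV"
        if "/" in gain_tok:
            gain_tok, units = gain_tok.split("/", 1)
        baseline = None
        if "(" in gain_tok:
            gain_tok, base_part = gain_tok.split("(", 1)
            baseline = int(base_part.rstrip(")"))
        gain = float(gain_tok) if gain_tok else 0.0
        if gain == 0.0:
            gain = 200.0  # WFDB default for unspecified gain
        if len(toks) > 4:
            spec.adc_zero = int(toks[4])
        spec.gain = gain
        spec.baseline = baseline if baseline is not None else spec.adc_zero
        spec.units = units
    if len(toks) > 8:
        spec.description = " ".join(toks[8:])
    return spec


def _read_dat(path: str, fmt: int, n_sig: int, n_samples: int) -> np.ndarray:
    """Return raw ADC integers of shape (n_samples, n_sig)."""
    raw = np.fromfile(path, dtype=np.uint8)
    if fmt == 16:
        data = raw.view("<i2")
        total = (len(data) // n_sig) * n_sig
        sig = data[:total].reshape(-1, n_sig).astype(np.int64)
    elif fmt == 212:
        n_pairs = len(raw) // 3
        b = raw[: n_pairs * 3].reshape(-1, 3).astype(np.int64)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(n_pairs * 2, dtype=np.int64)
        flat[0::2], flat[1::2] = first, second
        total = (len(flat) // n_sig) * n_sig
        sig = flat[:total].reshape(-1, n_sig)
    else:
        raise WfdbFormatError(f"unsupported WFDB signal format {fmt}")
    if n_samples:
        sig = sig[:n_samples]
    return sig


def read_signal(header_path: str) -> tuple[Header, np.ndarray]:
    """Read a record; returns header and physical samples (mV) per channel.

    All signals must live in a single .dat file of one format (true for
    MIT-BIH records).
    """
    hdr = read_header(header_path)
    if not hdr.signals:
        raise WfdbFormatError(f"{header_path!r} declares no signals")
    dat_name = hdr.signals[0].file_name
    fmt = hdr.signals[0].fmt
    if any(s.file_name != dat_name or s.fmt != fmt for s in hdr.signals):
        raise WfdbFormatError("multi-file/multi-format records not supported")
    dat_path = os.path.join(os.path.dirname(header_path) or ".", dat_name)
    adc = _read_dat(dat_path, fmt, hdr.n_sig, hdr.n_samples)
    phys = np.empty(adc.shape, dtype=np.float64)
    for ch, spec in enumerate(hdr.signals):
        phys[:, ch] = (adc[:, ch] - spec.baseline) / spec.gain
    return hdr, phys


def write_record(
    header_path: str,
    samples_mv: np.ndarray,
    fs: float,
    gain: float = 200.0,
    baseline: int = 0,
    fmt: int = 16,
    record_name: str | None = None,
) -> None:
    """Write a single- or multi-channel record in format 16."""
    if fmt != 16:
        raise WfdbFormatError("only format 16 is supported for writing")
    samples_mv = np.atleast_2d(np.asarray(samples_mv, dtype=np.float64))
    if samples_mv.shape[0] < samples_mv.shape[1]:
        samples_mv = samples_mv.T
    n_samples, n_sig = samples_mv.shape
    if record_name is None:
        record_name = os.path.splitext(os.path.basename(header_path))[0]
    dat_name = record_name + ".dat"
    adc = np.rint(samples_mv * gain + baseline).astype("<i2")
    adc.reshape(-1, n_sig).tofile(
        os.path.join(os.path.dirname(header_path) or ".", dat_name)
    )
    with open(header_path, "wt", encoding="ascii") as fh:
        fh.write(f"{record_name} {n_sig} {fs:g} {n_samples}\n")
        for _ in range(n_sig):
            fh.write(f"{dat_name} 16 {gain:g}({baseline})/mV 16 {baseline} 0 0 0\n")


def read_annotations(path: str) -> tuple[np.ndarray, list[int]]:
    """Read a MIT-format annotation file.

    Returns (sample_indices, type_codes) for every annotation, beats and
    non-beats alike; callers filter with :data:`BEAT_CODES`.
    """
    raw = np.fromfile(path, dtype=np.uint8)
    times: list[int] = []
    codes: list[int] = []
    t = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        lo, hi = int(raw[i]), int(raw[i + 1])
        i += 2
        code = hi >> 2
        interval = ((hi & 0x03) << 8) | lo
        if code == 0 and interval == 0:
            break  # EOF marker
        if code == _SKIP:
            if i + 4 > n:
                raise WfdbFormatError("truncated SKIP annotation")
            # PDP-11 long: high 16-bit word first, each word little-endian
            hi_w = struct.unpack("<H", bytes(raw[i : i + 2]))[0]
            lo_w = struct.unpack("<H", bytes(raw[i + 2 : i + 4]))[0]
            val = (hi_w << 16) | lo_w
            if val >= 1 << 31:
                val -= 1 << 32
            t += val
            i += 4
            continue
        if code == _AUX:
            i += interval + (interval & 1)  # aux string, padded to even
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        t += interval
        times.append(t)
        codes.append(code)
    return np.asarray(times, dtype=np.int64), codes


def write_annotations(path: str, indices: np.ndarray, codes=None) -> None:
    """Write a minimal MIT-format beat annotation file."""
    indices = np.asarray(indices, dtype=np.int64)
    if codes is None:
        codes = [1] * len(indices)
    out = bytearray()
    prev = 0
    for idx, code in zip(indices, codes):
        delta = int(idx) - prev
        if delta > 1023 or delta < 0:
            out += bytes([0, _SKIP << 2])
            val = delta & 0xFFFFFFFF
            out += struct.pack("<H", (val >> 16) & 0xFFFF)
            out += struct.pack("<H", val & 0xFFFF)
            delta = 0
        out += bytes([delta & 0xFF, (code << 2) | ((delta >> 8) & 0x03)])
        prev = int(idx)
    out += bytes([0, 0])  # EOF
    with open(path, "wb") as fh:
        fh.write(out)
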