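"""I/O for ECG records and beat annotations.

Two record formats are supported: WFDB (.hea/.dat, via the bundled
minimal reader) and a two-column CSV of ``sample_index,millivolts``.
Beat annotations come either from WFDB .atr files (non-beat annotation
types are dropped) or from plain text with one 0-based sample index per
line, optionally followed by a tab-separated label.

All amplitudes are carried in millivolts; all indices are 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from . import _wfdb

__all__ = [
    "EcgRecord",
    "BeatAnnotations",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class EcgRecord:
    """A single-lead ECG sample series in millivolts."""

    samples: np.ndarray
    fs: float
    record_id: str = ""
    lead: str | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if samples.ndim != 1 or len(samples) < 2:
            raise ValueError("record must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("record contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class BeatAnnotations:
    """Beat positions as 0-based sample indices, strictly increasing."""

    indices: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if len(idx) and idx[0] < 0:
            raise ValueError("negative beat index")
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("beat indices must be strictly increasing")
        if self.labels is not None and len(self.labels) != len(idx):
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.indices)


def read_record(
    path: str,
    format: str = "csv",
    channel: int = 0,
    fs: float | None = None,
) -> EcgRecord:
    """Read an ECG record from a WFDB header or CSV file.

    For WFDB the sampling rate and ADC gain/baseline come from the
    header; CSV amplitudes are taken as millivolts and *fs* must be
    supplied by the caller.
    """
    if format == "wfdb":
        hdr, phys = _wfdb.read_signal(path)
        if not 0 <= channel < phys.shape[1]:
            raise IndexError(
                f"channel {channel} out of range for {phys.shape[1]}-signal record"
            )
        lead = hdr.signals[channel].description or None
        return EcgRecord(phys[:, channel], hdr.fs, hdr.record_name, lead)
    if format == "csv":
        if fs is None:
            raise ValueError("csv records need an explicit fs")
        data = _load_csv(path)
        record_id = os.path.splitext(os.path.basename(path))[0]
        return EcgRecord(data[:, 1], fs, record_id)
    raise ValueError(f"unknown record format {format!r}")


def _load_csv(path: str) -> np.ndarray:
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    skip = 0
    try:
        [float(tok) for tok in first.strip().split(",")[:2]]
    except ValueError:
        skip = 1  # header row
    data = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path!r}: need two columns (index, millivolts)")
    return data


def write_record(record: EcgRecord, path: str) -> None:
    """Write a record as two-column CSV (index, millivolts)."""
    idx = np.arange(len(record.samples))
    np.savetxt(
        path,
        np.column_stack([idx, record.samples]),
        delimiter=",",
        fmt=("%d", "%.9f"),
        header="index,mV",
        comments="",
    )


def read_annotations(path: str, format: str = "text") -> BeatAnnotations:
    """Read beat annotations; WFDB non-beat annotation types are dropped."""
    if format == "wfdb":
        times, codes = _wfdb.read_annotations(path)
        keep = [i for i, c in enumerate(codes) if c in _wfdb.BEAT_CODES]
        idx = times[keep]
        labels = tuple(_wfdb.CODE_TO_SYMBOL.get(codes[i], "?") for i in keep)
        order = np.argsort(idx, kind="stable")
        return BeatAnnotations(idx[order], tuple(labels[i] for i in order))
    if format == "text":
        indices: list[int] = []
        labels: list[str] = []
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                try:
                    indices.append(int(parts[0]))
                except ValueError as exc:
                    raise ValueError(
                        f"{path!r} line {lineno}: not an integer index"
                    ) from exc
                labels.append(parts[1] if len(parts) > 1 else "")
        lab = tuple(labels) if any(labels) else None
        return BeatAnnotations(np.asarray(indices, dtype=np.int64), lab)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotations(ann: BeatAnnotations, path: str) -> None:
    """Write plain-text annotations, one index (+ optional label) per line."""
    with open(path, "wt", encoding="utf-8") as fh:
        for i, idx in enumerate(ann.indices):
            if ann.labels is not None and ann.labels[i]:
                fh.write(f"{idx}\t{ann.labels[i]}\n")
            else:
                fh.write(f"{idx}\n")
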