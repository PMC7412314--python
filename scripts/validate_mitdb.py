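#!/usr/bin/env python
"""Optional full-database validation against the MIT-BIH Arrhythmia set.

Requires a local copy of the database (48 records, .hea/.dat/.atr), e.g.
downloaded from PhysioNet ("mitdb").  Runs the detector on channel 0 of
every record, scores it against the reference annotations at the chosen
tolerance, and prints per-record deltas against published benchmark
counts.  The 2-min ventricular-flutter episode of record 207 is excluded
(via the VFON/VFOFF markers in its annotation file), as is conventional.

This is a soft validation tool, not a hard test: the published numbers
depend on unstated implementation details (notably the threshold
initialization), so small per-record differences are expected.

Usage:
    python scripts/validate_mitdb.py --data /path/to/mitdb [--tol-ms 300]
"""

import argparse
import os
import sys

import numpy as np

from etqrs import _wfdb
from etqrs.evaluate import MatchResult, compute_metrics, match_beats
from etqrs.pipeline import DetectorConfig, detect
from etqrs.signal_io import BeatAnnotations, read_record

# Published benchmark rows: record -> (tp, fp, fn)
REFERENCE_ROWS = {
    "100": (2273, 0, 0), "101": (1865, 1, 0), "102": (2187, 0, 0),
    "103": (2084, 0, 0), "104": (2230, 6, 0), "105": (2572, 32, 0),
    "106": (2027, 2, 0), "107": (2136, 0, 1), "108": (1763, 4, 0),
    "109": (2532, 0, 0), "111": (2123, 0, 1), "112": (2539, 0, 0),
    "113": (1795, 0, 0), "114": (1878, 3, 1), "115": (1953, 0, 0),
    "116": (2397, 1, 15), "117": (1535, 0, 0), "118": (2278, 1, 0),
    "119": (1987, 0, 0), "121": (1862, 0, 1), "122": (2476, 0, 0),
    "123": (1518, 0, 0), "124": (1618, 0, 0), "200": (2598, 0, 3),
    "201": (1943, 1, 20), "202": (2134, 0, 2), "203": (2957, 6, 23),
    "205": (2217, 0, 2), "207": (2217, 2, 115), "208": (2946, 3, 9),
    "209": (3005, 1, 0), "210": (2632, 4, 18), "212": (2748, 0, 0),
    "213": (3250, 0, 1), "214": (2262, 1, 0), "215": (3363, 0, 0),
    "217": (2208, 2, 0), "219": (2153, 0, 1), "220": (2048, 0, 0),
    "221": (2427, 0, 0), "222": (2474, 2, 9), "223": (2604, 0, 1),
    "228": (2053, 13, 0), "230": (2256, 0, 0), "231": (1571, 0, 0),
    "232": (1780, 7, 0), "233": (3078, 0, 1), "234": (2753, 0, 0),
}

_VFON, _VFOFF = 32, 33


def load_reference(atr_path: str):
    """Beat annotations plus flutter-episode exclusion intervals."""
    times, codes = _wfdb.read_annotations(atr_path)
    beats = times[[i for i, c in enumerate(codes) if c in _wfdb.BEAT_CODES]]
    exclusions = []
    start = None
    for t, c in zip(times, codes):
        if c == _VFON:
            start = int(t)
        elif c == _VFOFF and start is not None:
            exclusions.append((start, int(t)))
            start = None
    return BeatAnnotations(np.unique(beats)), exclusions


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", required=True,
                        help="directory with NNN.hea/.dat/.atr files")
    parser.add_argument("--records", nargs="*", default=None)
    parser.add_argument("--tol-ms", type=float, default=300.0)
    parser.add_argument("--chunk-state", choices=("persist", "reset"),
                        default="reset")
    args = parser.parse_args(argv)

    records = args.records or sorted(REFERENCE_ROWS)
    config = DetectorConfig(chunk_state=args.chunk_state)
    total = MatchResult(0, 0, 0)
    print("record  total    TP    FP    FN     Se     P+    Acc"
          "   dTP   dFP   dFN")
    for name in records:
        hea = os.path.join(args.data, name + ".hea")
        atr = os.path.join(args.data, name + ".atr")
        if not (os.path.exists(hea) and os.path.exists(atr)):
            print(f"{name}: missing files, skipped", file=sys.stderr)
            continue
        record = read_record(hea, "wfdb", channel=0)
        reference, exclusions = load_reference(atr)
        result = detect(record, config)
        tol = max(1, int(round(args.tol_ms / 1000.0 * record.fs)))
        m = match_beats(BeatAnnotations(result.beat_indices), reference,
                        tol, exclusions)
        met = compute_metrics(m)
        ref = REFERENCE_ROWS.get(name)
        dtp, dfp, dfn = ((m.tp - ref[0], m.fp - ref[1], m.fn - ref[2])
                         if ref else (0, 0, 0))
        print(f"{name:>6} {m.tp + m.fn:6d} {m.tp:5d} {m.fp:5d} {m.fn:5d} "
              f"{met.se:6.2f} {met.ppv:6.2f} {met.acc:6.2f} "
              f"{dtp:+5d} {dfp:+5d} {dfn:+5d}")
        total = MatchResult(total.tp + m.tp, total.fp + m.fp,
                            total.fn + m.fn)

    if total.tp:
        met = compute_metrics(total)
        print(f"{'all':>6} {total.tp + total.fn:6d} {total.tp:5d} "
              f"{total.fp:5d} {total.fn:5d} {met.se:6.2f} {met.ppv:6.2f} "
              f"{met.acc:6.2f}")
        goal = "met" if met.se >= 99.5 and met.ppv >= 99.5 else "NOT met"
        print(f"soft goal (Se and P+ >= 99.5%): {goal}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
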