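"""Published per-record MIT-BIH benchmark counts for this detector.

Each row: (record, total, tp, fp, fn, se, ppv, acc) with metrics as
printed (percent, two decimals).  Used purely as arithmetic fixtures for
the evaluation module; no ECG data is involved.  Note the record-205 row
carries an inconsistent published total (2656 vs tp+fn = 2219); metrics
are always recomputed from tp/fp/fn.
"""

PER_RECORD = [
    ("100", 2273, 2273, 0, 0, 100.00, 100.00, 100.00),
    ("101", 1865, 1865, 1, 0, 100.00, 99.95, 99.95),
    ("102", 2187, 2187, 0, 0, 100.00, 100.00, 100.00),
    ("103", 2084, 2084, 0, 0, 100.00, 100.00, 100.00),
    ("104", 2230, 2230, 6, 0, 100.00, 99.73, 99.73),
    ("105", 2572, 2572, 32, 0, 100.00, 98.77, 98.77),
    ("106", 2027, 2027, 2, 0, 100.00, 99.90, 99.90),
    ("107", 2137, 2136, 0, 1, 99.95, 100.00, 99.95),
    ("108", 1763, 1763, 4, 0, 100.00, 99.77, 99.77),
    ("109", 2532, 2532, 0, 0, 100.00, 100.00, 100.00),
    ("111", 2124, 2123, 0, 1, 99.95, 100.00, 99.95),
    ("112", 2539, 2539, 0, 0, 100.00, 100.00, 100.00),
    ("113", 1795, 1795, 0, 0, 100.00, 100.00, 100.00),
    ("114", 1879, 1878, 3, 1, 99.95, 99.84, 99.79),
    ("115", 1953, 1953, 0, 0, 100.00, 100.00, 100.00),
    ("116", 2412, 2397, 1, 15, 99.38, 99.96, 99.34),
    ("117", 1535, 1535, 0, 0, 100.00, 100.00, 100.00),
    ("118", 2278, 2278, 1, 0, 100.00, 99.96, 99.96),
    ("119", 1987, 1987, 0, 0, 100.00, 100.00, 100.00),
    ("121", 1863, 1862, 0, 1, 99.95, 100.00, 99.95),
    ("122", 2476, 2476, 0, 0, 100.00, 100.00, 100.00),
    ("123", 1518, 1518, 0, 0, 100.00, 100.00, 100.00),
    ("124", 1618, 1618, 0, 0, 100.00, 100.00, 100.00),
    ("200", 2601, 2598, 0, 3, 99.88, 100.00, 99.88),
    ("201", 1963, 1943, 1, 20, 98.98, 99.95, 98.93),
    ("202", 2136, 2134, 0, 2, 99.91, 100.00, 99.91),
    ("203", 2980, 2957, 6, 23, 99.23, 99.80, 99.03),
    ("205", 2656, 2217, 0, 2, 99.91, 100.00, 99.91),
    ("207", 2332, 2217, 2, 115, 95.07, 99.91, 94.99),
    ("208", 2955, 2946, 3, 9, 99.70, 99.90, 99.59),
    ("209", 3005, 3005, 1, 0, 100.00, 99.97, 99.97),
    ("210", 2650, 2632, 4, 18, 99.32, 99.85, 99.17),
    ("212", 2748, 2748, 0, 0, 100.00, 100.00, 100.00),
    ("213", 3251, 3250, 0, 1, 99.97, 100.00, 99.97),
    ("214", 2262, 2262, 1, 0, 100.00, 99.96, 99.96),
    ("215", 3363, 3363, 0, 0, 100.00, 100.00, 100.00),
    ("217", 2208, 2208, 2, 0, 100.00, 99.91, 99.91),
    ("219", 2154, 2153, 0, 1, 99.95, 100.00, 99.95),
    ("220", 2048, 2048, 0, 0, 100.00, 100.00, 100.00),
    ("221", 2427, 2427, 0, 0, 100.00, 100.00, 100.00),
    ("222", 2483, 2474, 2, 9, 99.64, 99.92, 99.56),
    ("223", 2605, 2604, 0, 1, 99.96, 100.00, 99.96),
    ("228", 2053, 2053, 13, 0, 100.00, 99.37, 99.37),
    ("230", 2256, 2256, 0, 0, 100.00, 100.00, 100.00),
    ("231", 1571, 1571, 0, 0, 100.00, 100.00, 100.00),
    ("232", 1780, 1780, 7, 0, 100.00, 99.61, 99.61),
    ("233", 3079, 3078, 0, 1, 99.97, 100.00, 99.97),
    ("234", 2753, 2753, 0, 0, 100.00, 100.00, 100.00),
]

# database totals: (total, tp, fp, fn, se, ppv, acc)
TOTAL_ROW = (109966, 109742, 91, 224, 99.80, 99.92, 99.71)

# per-16384-sample analysis units, flutter segment excluded:
# (total, tp, fn, fp, se, ppv, acc)
CHUNKED_ROW = (109496, 109386, 110, 91, 99.90, 99.92, 99.82)
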