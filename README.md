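# etqrs

Real-time QRS-complex detection for single-lead ECG, built around an
exponential nonlinear transform and a proportional–derivative (PD)
controlled adaptive threshold, plus evaluation tooling (Se / P+ / Acc)
and a seeded synthetic annotated-ECG generator so the whole pipeline is
testable without downloading any database.

## How it works

Five streaming stages per record:

1. **Preprocess** — 41-tap linear-phase Hamming-window FIR band-pass
   (5–15 Hz, constrained to zero DC gain), then the forward difference
   `d(n) = f(n+1) − f(n)`.
2. **Nonlinear transform** — `e(n) = |d(n)|·exp(−|d(n)|)` (or its
   first-order approximation `|d| − d²` for hardware parity), compressing
   large slopes so small/wide QRS complexes survive a shared threshold;
   then a centered moving sum over one nominal QRS duration (120 ms)
   yields the feature signal `s(n)`.
3. **Extreme-point detection** — consecutive 260-ms windows (with half a
   QRS width of side context); a point is an extreme iff it strictly
   dominates (or is dominated by) both neighbours at every lag up to
   half a QRS width.
4. **PD threshold** — the window threshold relaxes as
   `TH ← TH − a·(TH − TH_min) − b·ΔTH` (a = 0.5, b = 0.1,
   TH_min = 0.15), is interpolated per sample, and an extreme becomes a
   beat when the feature within ±15 samples exceeds 1.5× its threshold;
   a detection resets the threshold to the beat's feature value.
5. **Tall-T rejection** — two candidates closer than mean(RR)/3 are
   collapsed to the one with the larger feature value.

Records are consumed in 2^14-sample chunks. In `persist` mode all state
carries across chunk boundaries (chunked and full-record runs are
bit-identical); `reset` mode re-initializes per chunk to emulate
independent analysis units.

## CLI

```sh
# generate an annotated synthetic record (CSV + text annotations)
etqrs synth --duration 300 --seed 1 --preset clean --out scratch/rec

# detect beats (CSV needs --fs; .hea records are self-describing)
etqrs detect scratch/rec.csv --fs 360 --out scratch/det.ann --trace scratch/th.txt

# score detections against reference annotations
etqrs eval scratch/det.ann scratch/rec.ann --tol-ms 150
```

Presets: `clean`, `pvc`, `tall_t`, `noisy`, `rr_jump`. Detector options
can be set with `--config FILE` (flat `key = value` lines, e.g.
`detector.th_min = 0.15`, `pipeline.chunk_state = reset`; see
`DetectorConfig` for the full key list).

## Full-database validation (optional)

With a local copy of the MIT-BIH Arrhythmia Database (48 records,
`.hea/.dat/.atr`):

```sh
python scripts/validate_mitdb.py --data /path/to/mitdb --tol-ms 300
```

prints per-record Se / P+ / Acc and deltas against published benchmark
counts, excluding the conventional ventricular-flutter episode of
record 207. This is a soft comparison — the published figures depend on
unstated details such as the threshold initialization.
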