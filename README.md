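# somnoview

A library and CLI for reviewing patient-collected nocturnal physiology on a
single screen. It ingests multi-night device exports (SpO2, heart rate,
activity at ~1 Hz, plus episodic weight / blood-pressure / subjective-state
entries), partitions them into 4 pm–4 pm clinical days, detects sleep and
pulse-oximeter-wear periods, flags 30-minute threshold-violation blocks per
channel, and renders a three-layer hierarchical display (24-h overview →
8-h violation blocks → 30-min raw waveforms) as deterministic SVG. It also
computes the usability statistics used to evaluate such displays: System
Usability Scale scores with the Lewis–Sauro learnability/usability
subscales, a one-sample t-test against the literature benchmark of 68, and
the two-way mixed-effects consistency intraclass correlation ICC(3,1) with
exact F-based confidence bounds.

Default thresholds: SpO2 < 92 %, heart rate outside 60–100 bpm (either side
may flag, both can in one block), and 30-minute mean activity > 12 vector
magnitude units. All comparisons are strict; blocks lie on a grid anchored
at the 16:00 day start, and only blocks overlapping the sleep period (first
to last 30-min slot containing SpO2 or heart-rate data) are reported.

A seeded synthetic-data module generates multi-night heart-failure-like
records with planted desaturations, brady/tachycardia episodes and activity
bouts, together with a ground-truth log of exactly which blocks must flag —
so the whole pipeline is testable offline.

## CLI

```sh
# generate a 6-night synthetic patient into a file-backed store
somnoview simulate --seed 42 --out store/

# list patients; detect violations; render one day's screen
somnoview list store/
somnoview detect store/ synthetic-001 --out summaries.json
somnoview render store/ synthetic-001 --day 2 --out day2.svg
somnoview render store/ synthetic-001 --day 2 --window-start 23:00 --block 02:30 --out day2.svg

# ingest real device CSV exports described by a JSON manifest
somnoview ingest --manifest exports/manifest.json --out store/

# score SUS questionnaires (+ optional ICC from a ratings matrix)
somnoview sus sus.csv --ratings ratings.csv --round-display
```

Threshold flags (`--spo2-low`, `--hr-low`, `--hr-high`, `--activity-high`,
`--block-minutes`) are accepted by `detect` and `render`. Logs go to
stderr; data to files/stdout.

The store keeps two CSV tables per patient — `continuous.csv`
(`timestamp,channel,value`) and `episodic.csv` (`timestamp,kind,key,value`)
— plus a JSON manifest; round-trips are exact. Channel exports use a
`timestamp,value` header; SUS files use `respondent_id,item1..item10`;
ratings matrices have one target row and one rater column each.

## Layout

- `src/somnoview/core_model.py` — domain types, validation, clinical-day partitioning
- `src/somnoview/io_store.py` — CSV readers/writers, file-backed two-table store
- `src/somnoview/detection.py` — sleep/wear detection, violation blocking
- `src/somnoview/render.py` — scene building and SVG emission
- `src/somnoview/synthetic.py` — seeded generator with ground-truth event log
- `src/somnoview/usability_stats.py` — SUS, subscales, t-test, ICC(3,1)
- `src/somnoview/cli.py` — `somnoview` command group
- `tests/` — unit, property and acceptance suites
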