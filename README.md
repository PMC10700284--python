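# obskit

Headless tooling for **keystroke-coded behavioral observation** — the data
pipeline used by behavior-analytic clinicians and researchers who score
therapy sessions by pressing keys bound to target behaviors, check their
measurement with a second independent observer, and (optionally) collect
wrist-worn physiological signals alongside.

obskit is a library plus a small CLI. It covers the full pipeline with no
GUI, no hardware and no network:

* **Keystroke schemas (KSFs)** — XLSX workbooks binding single keys to
  named behaviors, either *frequency* (one press = one instance) or
  *duration* (presses toggle an episode open/closed), plus an ordered
  list of experimental conditions. Load, validate, extend, and regenerate
  clean revisions.
* **Event recording** — replay a timestamped keypress log through a
  pause-aware state machine: `ESC` starts, `LCTRL` toggles pause (the
  session clock freezes), `BKSP`/`RCTRL` undo/redo the last committed
  event, an optional cap ends the session automatically. Event times are
  *session seconds*, which exclude paused wall time.
* **Session storage** — one self-contained JSON document per session
  (metadata, events, pauses, and a schema snapshot), named
  `{number} {assessment[:2]} {condition[:2]}{DDMYYYY}{_R?}`, organized
  under a `{Concern} {Phase}/{Export,Graph,KSF,Raw Data}` directory tree.
* **Interobserver agreement (IOA)** — windowed coefficients between a
  primary and a reliability record, and a three-tab XLSX report.
* **Wearable channels** — EDA, BVP (photoplethysmography), 3-axis
  accelerometry and temperature recordings: session alignment, summary
  statistics, skin-conductance-response counting, and heart-rate /
  inter-beat-interval extraction.
* **Synthetic fixtures** — seeded generators for keypress logs (Poisson),
  physiological channels with known ground truth, and observer pairs with
  a controlled disagreement model, so everything above is testable.

## Agreement coefficients

Events are binned into half-open windows $[kw, (k+1)w)$ of size $w$
seconds (the final window may be partial). For a frequency key with
per-window counts $p_k$ and $r_k$ over $N$ windows:

* total-count IOA $= 100\cdot \min(P,R)/\max(P,R)$ with
  $P=\sum p_k,\ R=\sum r_k$;
* exact count-per-interval IOA
  $= \tfrac{100}{N}\,\#\{k : p_k = r_k\}$;
* block-by-block IOA
  $= \tfrac{100}{N}\sum_k \min(p_k,r_k)/\max(p_k,r_k)$.

A $0/0$ window counts as perfect agreement — the conventional choice,
which inflates agreement for rare behaviors; the report states every
coefficient side by side so this is visible. Duration keys are scored on
per-window overlap *seconds* (total and block-by-block only).

## Worked example

Generate a synthetic primary/reliability pair in which the second
observer misses each event with probability 0.2, then compute agreement
at a 10-second window:

```
$ obskit synth pair --duration 120 --rate 0.2 --drop 0.2 --seed 3 \
    --out-primary p.json --out-reliability r.json
$ obskit ioa --primary p.json --reliability r.json --window 10 --out report.xlsx
```

Inspecting the same pair through the library:

```
primary events: 25 freq + 4 dur
reliability events: 21 freq + 4 dur
hitting      frequency total=  84.0  exact=66.7  block=  89.3
kicking      frequency total= 100.0  exact=100.0  block= 100.0
aggression   duration  total= 100.0  exact=None  block= 100.0
```

The reliability observer missed 4 of 25 `hitting` instances, so the
total-count coefficient is $100\cdot 21/25 = 84.0$; window-level
disagreement drives the exact coefficient lower (66.7 %) than the
block-by-block mean ratio (89.3 %). `kicking` was never scored by either
observer, so the $0/0$ convention reports 100 % — exactly the rare-behavior
inflation discussed above. `report.xlsx` holds the raw primary events,
the raw reliability events, and these coefficients on three tabs.

The same CLI records sessions from token logs (`obskit record`), exports
CSV (`obskit export-csv`), fills per-session keystroke bins into a KSF
workbook (`obskit analyze`), and computes wearable-channel features
(`obskit e4-metrics`).

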