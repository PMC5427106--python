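# ethoscore

A scriptable toolkit for manual behavioral scoring in rodent tests.
Timestamped keystroke logs become validated bout timelines; timelines yield
per-behavior measures (total time, bout/occurrence counts, latencies) and
test-specific indices — FST latencies, % time/entries in open arms for the
elevated plus maze, discrimination and preference indices for novel object
recognition.  Timelines render as color-coded per-animal "visual maps"
(png) for training and audit, and two raters' scorings of the same animals
can be compared with per-measure Pearson correlations plus a sample-wise
timeline concordance (percent agreement and Cohen's kappa).  A simulator
generates synthetic sessions and noisy second-rater replicas so the whole
pipeline is testable without animal data.

## Concepts

- **Ethogram** — the template for one test: behaviors (`state` behaviors
  are mutually exclusive and carry duration; `point` behaviors are
  instantaneous counted events), each with a key binding and an RGB color,
  plus a session/trial scheme.  Built-in templates: `FST` (immobility
  blue, swimming red, climbing black, head-shake green point events;
  2 sessions x 300 s), `NOR`, `EPM`.  Key bindings and EPM colors are
  package defaults; customize freely.
- **Scoring** — toggle semantics: a state keystroke at time *t* closes the
  open bout and opens a new one; the last bout closes at trial end; point
  keystrokes don't disturb the open bout.  Bouts are half-open intervals
  `[start, end)`, so adjacent bouts partition time exactly.  Events past
  the trial duration are rejected, never clamped.
- **Keystroke log format** — UTF-8 text, one `<t_seconds><TAB><key>` per
  line, `#` comments.
- **Projects** — a single-file SQLite store with subjects, descriptors,
  groups (assignable after scoring), ethograms and trials keyed by
  (subject, test, session, trial, rater); plus a portable JSON text export.

## CLI

```sh
ethoscore template show FST
ethoscore template new --from FST --out my.etho
ethoscore score --etho my.etho --log rat1.tsv --subject R1 --rater NK --project p.db
ethoscore export --project p.db --test FST --out results.csv --bins 60 --maps-dir maps/
ethoscore map --project p.db --test FST --out-dir maps/ --collate all.png
ethoscore agree --project p.db --test FST --raters A B
```

`export` writes RFC-4180 csv, one row per (subject, session, trial, rater,
segment): group and descriptor columns, then per-behavior
`total_s/count/latency_s/latency_censored` blocks, `n_events`, and the
test's index columns.  Latencies of behaviors that never occurred are
censored at trial duration with `latency_censored=true`.  Undefined
indices (zero denominators) are blank cells.  Visual maps are written one
png per animal/trial, named
`<project>_<subject>_<test>_s<session>t<trial>_<rater>.png`.

## Library example

```python
import ethoscore as es

etho = es.builtin_template("FST")
events = [es.KeyEvent(0, "s"), es.KeyEvent(30, "h"), es.KeyEvent(120, "i")]
trial = es.keystrokes_to_timeline(events, etho, 300.0, subject_id="R1")
ms = es.summarize_trial(trial, etho)
print(ms.total("immobility"), ms.latency("immobility"), ms.n_events)

img = es.render_map(trial, etho)           # PIL image, 2 px/s by default
seg = es.slice_segment(trial, 60.0, 120.0)  # second minute only
```

Simulation (semi-Markov bout generator + rater-noise model):

```python
model = es.fst_like_model()
a = es.simulate_trial(model, etho, 300.0, seed=1, subject_id="R1", rater_id="A")
b = es.simulate_second_rater(a, es.RaterNoise(jitter_sigma_s=0.5,
                                              mislabel_prob=0.02, seed=2))
print(es.timeline_concordance(a, b))
```

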