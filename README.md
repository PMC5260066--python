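# spectratrack

Content-addressed processing-history tracking for magnetic resonance
spectroscopy (MRS) quantitation workflows.

## The problem

Turning an in-vivo MRS acquisition into metabolite concentration estimates
is an interactive, trial-and-error process: a free induction decay (FID)
is loaded, preprocessed (apodization, zero-filling, phasing, scaling, ...),
and finally fitted against a metabolite basis set. After several attempts
it is easy to lose track of *which* processing chain and *which* parameter
files produced a given result — and without that record the result is not
reproducible. spectratrack is a provenance layer for exactly this setting:
it records every processing action, every parameter, every file and every
quantitation result in an embedded relational store, fully in the
background, and lets you query, replay and export that history later.

## How it works

* **Files are identified by content, not location.** Every tracked file's
  identity is the SHA-256 of its bytes. Loading the same data from a
  different path, or from a file that has since been moved, resolves to
  the same record. Parameter and result files are archived in managed
  directories under their own hash as filename, so any later corruption
  is detectable by re-hashing.
* **Nine-table audit trail.** Five history tables (`ACTIONS`, `PARAMS`,
  `RESULTS`, `FILES`, `FILES_ACTIONS`), two comment tables and two macro
  tables, in a single SQLite file. History is append-only. Saving a
  processed file records a lineage pointer (`FILES.child`) to the file it
  was derived from, so the full derivation chain of any result can be
  walked back to the raw data.
* **One call per action.** A processing routine describes what it did as a
  `ProvenanceEntry` (action key, ordered parameters with units, result
  file for quantitations); `record_action` writes the complete relational
  footprint atomically.
* **Macros and replay.** Any ordered selection of past actions can be
  stored as a named macro and re-executed later — with or without
  parameter overrides — and every replayed step is recorded as new
  history.
* **Reproducibility bundles.** For any quantitation result, one zip with
  the original data file, the rendered processing history
  (`processing.batch`), every parameter file and the result itself, plus
  a manifest of content hashes.

A synthetic FID layer (sum of damped complex exponentials
`s(t) = Σ a_m exp((i2πf_m − d_m)t) + noise`, canonical text formats, four
deterministic preprocessing plugins and a linear least-squares mock
quantitation) exercises the whole tracker without any scanner data.

## Worked example

```bash
$ spectratrack --store study1 demo --work work --seed 7
ACTIONS	5
PARAMS	4
RESULTS	1
FILES	2
FILES_ACTIONS	5
MACRO	1
MACRO_contents	2
ACTIONS_comment	0
RESULTS_comment	0
data_hash	b21a470aa308d4e478db9e2f7a2ff5a213a7e85edf5066c5211f9d063168a762
saved_hash	ae08449f120f72fe6c73e69c1297d5c43e0de046c192976ad2b10153822a18be
result_hash	8bdce26766ed7dbf270231c38830f6e1da4237507e0ace450273356116018b7f
bundle	work/bundle.zip
amplitude[NAA]	1.998793
amplitude[Cr]	0.999766
amplitude[Cho]	0.598697
```

The demo simulates a three-metabolite FID with generating amplitudes
(2.0, 1.0, 0.6), loads it, apodizes and phases it, fits it against the
basis, saves the processed file and exports the bundle. The row counts are
the complete relational footprint of that session: five actions
(load, two preprocessing steps, quantitation, save), four parameter rows,
one result, and two file records — the raw file and its processed child.
The fitted amplitudes land within the noise of the generating values.

The recorded history of the raw file:

```bash
$ spectratrack --store study1 history 1 --mode all
# spectratrack batch v1
ACTION LOAD_FILE 2020-01-01T00:00:00Z
ACTION APODIZE 2020-01-01T00:00:01Z
PARAM exponential line broadening [Hz] = 5.0
ACTION PHASE0 2020-01-01T00:00:02Z
PARAM zero-order phase [deg] = 30.0
ACTION QUANTIFY 2020-01-01T00:00:03Z
PARAM Metabolite list file [.ml] = basis.ml HASH 25ff1f10...
PARAM Processing options file [.op] = quant.op HASH 68f7c6f3...
RESULT demo_QUANT.results HASH 8bdce267...
```

Replaying the session's recorded macro on the raw data reproduces the
saved file bit for bit — its hash equals the `saved_hash` above:

```bash
$ spectratrack --store study1 macro run --name demo-preprocessing \
      --data work/data.fid --save-as work/replayed.fid
work/replayed.fid	ae08449f120f72fe6c73e69c1297d5c43e0de046c192976ad2b10153822a18be
```

The same flows are available as a library (`init_store`,
`register_loaded_file`, `record_action`, `history_with_parents`,
`replay_macro`, `export_result_bundle`, ...); see `docs/methods.md`.

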