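# Methods

## The provenance model

spectratrack treats an MRS processing session as an append-only event log
over content-addressed files. Three kinds of events exist:

1. **Load** — a data file enters a session. Its SHA-256 is looked up in
   `FILES`; a known hash resolves to the existing `ID_file` (so duplicate
   copies of the same bytes are one logical file), an unknown hash gets a
   new row with `child = -1`. Every load, including a load of known
   content, appends a `LOAD_FILE` action: loads are auditable events in
   their own right.
2. **Action** — a processing routine ran. One `ACTIONS` row (key ≤ 64
   chars + timestamp), one `PARAMS` row per parameter in call order, a
   `FILES_ACTIONS` link per target file, and — iff the routine is a
   quantitation — an ingested result file plus its `RESULTS` row. The
   whole write is one transaction; all referenced file content is read
   before the first row is written, so I/O failures cannot leave partial
   history.
3. **Save** — the processed data was written to disk by the caller. The
   new file gets a `FILES` row whose `child` column holds the id of the
   file it was derived from, plus a `SAVE` action. Lineage is the chain of
   these pointers; `history_with_parents` walks it root-first and
   concatenates each ancestor's listing.

Identity is always the content hash, never the path. `FILES.path` records
where the file lived at registration time and may legitimately go stale;
lookups by hash still succeed after a move. Hashes are stored and compared
as 64 lowercase hex characters, and `FILES.hash` is unique: if a save
reproduces byte-identical previously-registered content (which macro
replay does by design), the existing id is reused and only the `SAVE`
event is appended.

The two comment tables carry free-text comments plus a three-state
approval flag (`approved` / `not-approved` / unset). The flag is the one
deliberate exception to append-only: re-approving overwrites in place,
last write wins, because it is review metadata rather than history.

### The session registry

The "open files" registry is a per-process, in-memory structure mapping
each open `ID_file` to the id of the `LOAD_FILE`/`SAVE` event that opened
it. That entry id defines the *current session* boundary: a data-mode
session query returns the actions linked to the file with
`ID_action >=` the entry id, so the opening event itself is included, and
closing + reopening a file restarts its session. The registry is never
persisted — it describes a live session, not history. (The CLI, whose
"session" spans multiple processes, snapshots its own continuity state to
`.session.json` under the store root; that file is a CLI convenience and
not part of the provenance model.)

### Result-mode queries and bundles

A result hash resolves through `RESULTS.ID_action` to the producing
action and, via its file link, to the file it was applied to. The
result-mode session listing is that file's history truncated at and
including the quantitation. The reproducibility bundle extends this with
the lineage: it packs the *root ancestor's* data file (verified against
its recorded hash before packing), the batch rendering of the
history-with-parents up to the quantitation, every file-valued parameter
of those actions (taken from the managed hash-named copies), the result
file, and a `MANIFEST.txt` of `name → hash → role` lines. Missing or
altered managed files abort the export with the offending hash named.

## The batch dialect

Histories and macros render to a line-oriented UTF-8 text format:

```
# spectratrack batch v1
ACTION <key> <ISO-8601-UTC>
PARAM <description> = <value>[ HASH <64-hex>]
RESULT <basename> HASH <64-hex>
```

Rendering is deterministic (byte-identical for identical inputs) and
parseable back; the parser splits `PARAM` lines at the *last* `" = "`, so
descriptions may contain `" = "` but values must not. File-valued
parameters render by basename: the hash, not the absolute path of the
recording machine, is the portable identity, and replay resolves file
parameters through the managed copy first, falling back to the recorded
path. `LOAD_FILE`/`SAVE` events may appear in a full history rendering;
replay-from-text skips them.

## Macros and replay

A macro stores *references* (`MACRO_contents.ID_action`) to past actions,
never copies — recorded history is the single source of truth, and since
deletion is unsupported a macro can never dangle. File events cannot join
a macro. Replay resolves each action key against a plugin registry
(pre-flight: unknown keys and out-of-range override indices fail before
anything executes), binds recorded parameter values positionally to the
plugin signature (numbers via `float`, files via managed copy), executes,
and records each step through the ordinary recording path. Overrides are
applied at replay time and recorded as new history; the original rows are
immutable, which the tests check by byte-comparing the pre-existing
`PARAMS` rows before and after an overridden replay.

## Synthetic data

The generator emulates a single-voxel proton MRS free induction decay as a
sum of damped complex exponentials,

    s(t_k) = Σ_m a_m · exp((i·2π·f_m − d_m)·t_k) + ε_k,

with `t_k = k·dt` (dt in ms, converted to seconds for the frequency
math) and ε complex circular Gaussian noise of standard deviation
`noise_sd` per component, drawn from a seeded generator. Defaults used by
the demo and the acceptance measurements: three metabolite-like
components ("NAA", "Cr", "Cho") at −97.0, −146.0 and −151.5 Hz offsets
with 8–10 s⁻¹ damping at a 63.86 MHz transmitter, amplitudes
(2.0, 1.0, 0.6), 512 points at 0.5 ms, `noise_sd = 0.01` — a clean,
well-conditioned short-TE-like toy signal. What it deliberately does
*not* emulate: macromolecular baselines, eddy-current distortions,
frequency drift, residual water, multiplet structure, or any acquisition
physics. Passing tests therefore demonstrate the correctness of the
*tracking* machinery on realistic workflow shapes, not the quality of any
spectral fitting on real data.

### Canonical serialization

Every numeric field in the text formats (FID, basis, options, results) is
written as lowercase scientific notation with 17 significant digits
(`%.16e`), tab-separated, `\n`-terminated, UTF-8. 17 significant digits
round-trip IEEE doubles exactly, so write∘read∘write is byte-identical
and equal datasets always hash equally — the property the tracker's
deduplication and the byte-exact replay check rest on.

### Processing operators

Four deterministic plugins: `ZERO_FILL` (append zeros to a target length
≥ current), `APODIZE` (multiply by `exp(−π·lb·t)`, lb ≥ 0 Hz), `PHASE0`
(multiply by `exp(i·φ)`, φ in degrees), `SCALE` (non-zero constant). Each
emits a provenance entry with exactly one described parameter. Parameter
values are recorded with Python's shortest round-trip float repr, so a
replayed `float(value)` is bit-equal to the original and the replayed
output file hashes identically.

### Mock quantitation

Amplitudes are estimated by complex linear least squares of the
(optionally re-phased) FID on the basis signals
`exp((i·2πf_m − d_m)t)`; reported amplitudes are the real parts of the
solution (the generating model has real amplitudes). Rank-deficient
designs (duplicated basis signals) are rejected. This is a transparent
stand-in for a real spectral fitting algorithm: what the tracker records
— two file parameters (.ml basis list, .op options) and one result file —
is the provenance shape that matters, and the linear model makes the
estimator exactly checkable: noiseless fits recover the generating
amplitudes to ≤ 1e-9 relative error, and noisy fits match an independent
normal-equations solve to ≤ 1e-9 (both asserted in the tests and
measured by `scripts/acceptance.py`).

The demo's quantitation basis file carries dampings increased by `π·lb`
relative to the generating basis, compensating the extra decay the
`APODIZE` step introduced, so the demo's printed amplitudes land near the
generating truth instead of being attenuation-biased.

## Numerical and design choices

* **Storage engine**: SQLite via the standard library — an embedded,
  single-file SQL store; the schema, not the engine, is the contract.
  Plain `INTEGER PRIMARY KEY` columns give incremental, never-reused ids
  without auxiliary engine tables.
* **Timestamps**: ISO 8601 UTC at second precision; non-decreasing in id
  order. The store accepts an injectable clock; the scripted demo uses a
  deterministic one (fixed start, +1 s per event) so its entire output,
  rendered timestamps included, is byte-reproducible. The library default
  is the wall clock.
* **child sentinel**: the literal `-1` (not NULL) marks a file with no
  recorded parent, making the default printable and testable.
* **Reserved keys**: `LOAD_FILE` and `SAVE` are written by the registry
  itself and rejected as plugin or macro keys.
* **Concurrency**: single-writer, per-user desktop contract; concurrent
  writers are out of scope.
* **Degenerate inputs**: malformed hashes, unknown ids, empty
  histories/macros and bad plugin parameters raise typed validation
  errors; filesystem failures surface as `OSError`; a corrupt or foreign
  database file raises a schema error rather than being silently
  re-initialized.
* **Problem sizes**: the test suite and acceptance script use 128–512
  point FIDs, lineage chains of depth up to 10 and single-session stores —
  sizes at which every property (dedup counts, lineage concatenation,
  byte-exact replay) is exhaustively checkable while the full suite runs
  in seconds.

## Known limitations

* No deletion or editing of recorded history (by design), and therefore
  no redaction mechanism.
* `FILES.path` staleness is accepted, and bundle export requires the root
  ancestor's data file to still exist at its recorded path with its
  recorded content (data files are not copied into managed storage).
* One result file per quantitation action is assumed by the queries and
  the bundle exporter.
* No server mode, encryption, or migration tooling; a store is one local
  directory.
* The macro text dialect forbids `" = "` inside parameter values.
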