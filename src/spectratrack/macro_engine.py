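"""Macros: named, replayable ordered subsets of past actions.

A macro is stored purely as references — one MACRO row plus one
MACRO_contents row per action id, in order — so recorded history is the
single source of truth and can never diverge from its macros. Replay
resolves each action's macro key against a registry of processing plugins,
binds the recorded parameter values (optionally overridden per call),
executes, and records every executed step as *new* history through the
ordinary recording path; the original rows are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .action_recorder import ProvenanceEntry, record_action
from .errors import (
    ExecutionError,
    ResolutionError,
    ValidationError,
)
from .file_registry import RESERVED_ACTIONS, OpenFilesRegistry, managed_file_path
from .history_query import (
    HistoryItem,
    ParsedAction,
    item_for_action,
    render_batch,
)
from .schema_store import ProvenanceStore

ParamKind = str  # 'number' | 'text' | 'file'


@dataclass(frozen=True)
class PluginSpec:
    """One registered processing routine.

    ``func`` implements the action: called as ``func(dataset, *values)``
    with values bound positionally from the recorded parameters (numbers as
    float, files as resolved paths), it returns
    ``(new_dataset, ProvenanceEntry)`` for preprocessing plugins or
    ``(result_path, ProvenanceEntry)`` when ``is_quantitation`` is set —
    the same carrier-object contract live processing uses, so replayed
    steps are recorded identically to original ones.
    """

    key: str
    signature: tuple[tuple[str, ParamKind], ...]  # (description, kind) per param
    func: Callable
    is_quantitation: bool = False


class PluginRegistry:
    """Macro-key → plugin lookup table."""

    def __init__(self) -> None:
        self._plugins: dict[str, PluginSpec] = {}

    def __contains__(self, key: str) -> bool:
        return key in self._plugins

    def get(self, key: str) -> PluginSpec:
        if key not in self._plugins:
            raise ResolutionError(f"no plugin registered for macro key {key!r}")
        return self._plugins[key]

    def keys(self) -> tuple[str, ...]:
        return tuple(self._plugins)


def register_plugin(registry: PluginRegistry, spec: PluginSpec) -> PluginRegistry:
    """Register a plugin; reserved and duplicate keys are rejected."""
    key = str(spec.key)
    if not key or len(key) > 64:
        raise ValidationError(f"invalid macro key {key!r}")
    if key in RESERVED_ACTIONS:
        raise ValidationError(f"macro key {key!r} is reserved for the file registry")
    if key in registry:
        raise ValidationError(f"macro key {key!r} is already registered")
    registry._plugins[key] = spec
    return registry


# ---------------------------------------------------------------------------
# macro storage


def create_macro(
    store: ProvenanceStore,
    name: str,
    comment: str,
    action_ids: Sequence[int],
) -> int:
    """Store a named ordered selection of past actions as a macro.

    Every referenced action must exist and be a plugin action (the
    LOAD_FILE/SAVE bookkeeping events cannot be replayed). Returns the new
    ``ID_macro``, shared by the MACRO row and its MACRO_contents rows.
    """
    if not str(name).strip():
        raise ValidationError("macro name must be non-empty")
    if not action_ids:
        raise ValidationError("a macro needs at least one action")
    if store.query_one("SELECT 1 FROM MACRO WHERE name = ?", (str(name),)) is not None:
        raise ValidationError(f"macro name {name!r} is already in use")
    ids = [int(a) for a in action_ids]
    for aid in ids:
        row = store.query_one(
            "SELECT action FROM ACTIONS WHERE ID_action = ?", (aid,)
        )
        if row is None:
            raise ValidationError(f"unknown action id {aid}")
        if row["action"] in RESERVED_ACTIONS:
            raise ValidationError(
                f"action {aid} ({row['action']}) is a file event and cannot join a macro"
            )
    with store.transaction():
        row = store.query_one("SELECT COALESCE(MAX(ID_macro), 0) FROM MACRO")
        id_macro = row[0] + 1
        store.execute(
            "INSERT INTO MACRO (ID_macro, name, comment) VALUES (?, ?, ?)",
            (id_macro, str(name), str(comment)),
        )
        for pos, aid in enumerate(ids):
            store.execute(
                "INSERT INTO MACRO_contents (ID_macro, ID_action, position)"
                " VALUES (?, ?, ?)",
                (id_macro, aid, pos),
            )
    return id_macro


@dataclass(frozen=True)
class MacroRecord:
    id_macro: int
    name: str
    comment: str


def list_macros(store: ProvenanceStore) -> list[MacroRecord]:
    return [
        MacroRecord(r["ID_macro"], r["name"], r["comment"])
        for r in store.query_all(
            "SELECT ID_macro, name, comment FROM MACRO ORDER BY ID_macro"
        )
    ]


def _macro_row(store: ProvenanceStore, id_macro: int):
    row = store.query_one(
        "SELECT ID_macro, name, comment FROM MACRO WHERE ID_macro = ?",
        (int(id_macro),),
    )
    if row is None:
        raise ValidationError(f"unknown macro id {id_macro}")
    return row


def find_macro_by_name(store: ProvenanceStore, name: str) -> MacroRecord:
    row = store.query_one(
        "SELECT ID_macro, name, comment FROM MACRO WHERE name = ?", (str(name),)
    )
    if row is None:
        raise ValidationError(f"unknown macro name {name!r}")
    return MacroRecord(row["ID_macro"], row["name"], row["comment"])


def macro_action_ids(store: ProvenanceStore, id_macro: int) -> list[int]:
    """Action ids of a macro in stored position order."""
    _macro_row(store, id_macro)
    rows = store.query_all(
        "SELECT ID_action FROM MACRO_contents WHERE ID_macro = ? ORDER BY position",
        (int(id_macro),),
    )
    return [r["ID_action"] for r in rows]


def macro_items(store: ProvenanceStore, id_macro: int) -> list[HistoryItem]:
    return [item_for_action(store, aid) for aid in macro_action_ids(store, id_macro)]


def export_macro_text(
    store: ProvenanceStore, id_macro: int, out_path: str | Path | None = None
) -> str:
    """Render a macro as batch text (same dialect as processing.batch).

    Deterministic: exporting the same macro twice yields identical bytes.
    Optionally also written to ``out_path``.
    """
    text = render_batch(macro_items(store, id_macro))
    if out_path is not None:
        Path(out_path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# replay


@dataclass(frozen=True)
class ReplayStep:
    original_id_action: int | None  # None when replaying from a batch file
    new_id_action: int
    action: str
    applied_overrides: tuple[tuple[int, str], ...]  # (param index, new value)


@dataclass
class ReplayReport:
    """Outcome of a macro replay: the new history plus the final payload."""

    steps: list[ReplayStep] = field(default_factory=list)
    dataset: object | None = None
    result_path: Path | None = None


def _bind_values(
    spec: PluginSpec,
    values: Sequence[str],
    hashes: Sequence[str],
    store: ProvenanceStore,
) -> list:
    if len(values) != len(spec.signature):
        raise ValidationError(
            f"plugin {spec.key!r} expects {len(spec.signature)} parameters,"
            f" got {len(values)}"
        )
    bound = []
    for (desc, kind), value, h in zip(spec.signature, values, hashes):
        if kind == "number":
            try:
                bound.append(float(value))
            except ValueError as exc:
                raise ValidationError(
                    f"parameter {desc!r} of {spec.key!r} is not numeric: {value!r}"
                ) from exc
        elif kind == "file":
            # prefer the immutable managed copy; fall back to the recorded path
            path = None
            if h:
                try:
                    path = managed_file_path(store, h, "parameter")
                except Exception:
                    path = None
            if path is None:
                path = Path(value)
                if not path.exists():
                    raise ValidationError(
                        f"file parameter {desc!r} of {spec.key!r} cannot be resolved"
                        f" (no managed copy, path {value!r} missing)"
                    )
            bound.append(path)
        else:
            bound.append(str(value))
    return bound


def _execute_sequence(
    store: ProvenanceStore,
    registry: OpenFilesRegistry,
    plugins: PluginRegistry,
    sequence: Sequence[tuple[int | None, str, list[str], list[str]]],
    dataset,
    id_file: int,
    overrides: Mapping[tuple[int, int], object] | None,
) -> ReplayReport:
    overrides = dict(overrides or {})
    # pre-flight: resolve every key and validate every override index
    specs = [plugins.get(key) for _, key, _, _ in sequence]
    for (pos, idx), _ in overrides.items():
        if not (0 <= pos < len(sequence)):
            raise ValidationError(f"override position {pos} out of range")
        if not (0 <= idx < len(sequence[pos][2])):
            raise ValidationError(
                f"override parameter index {idx} out of range for step {pos}"
            )

    report = ReplayReport(dataset=dataset)
    for pos, ((orig_aid, key, values, hashes), spec) in enumerate(
        zip(sequence, specs)
    ):
        applied: list[tuple[int, str]] = []
        step_values = list(values)
        for (opos, idx), new_value in overrides.items():
            if opos == pos:
                step_values[idx] = str(new_value)
                applied.append((idx, str(new_value)))
        bound = _bind_values(spec, step_values, hashes, store)
        try:
            payload, entry = spec.func(report.dataset, *bound)
        except ValidationError:
            raise
        except Exception as exc:
            raise ExecutionError(f"plugin {key!r} failed: {exc}") from exc
        if not isinstance(entry, ProvenanceEntry):
            raise ExecutionError(f"plugin {key!r} returned no provenance entry")
        new_aid = record_action(store, registry, entry, [id_file])
        if spec.is_quantitation:
            report.result_path = Path(payload)
        else:
            report.dataset = payload
        report.steps.append(
            ReplayStep(orig_aid, new_aid, key, tuple(sorted(applied)))
        )
    return report


def replay_macro(
    store: ProvenanceStore,
    registry: OpenFilesRegistry,
    plugins: PluginRegistry,
    id_macro: int,
    dataset,
    id_file: int,
    overrides: Mapping[tuple[int, int], object] | None = None,
) -> ReplayReport:
    """Re-execute a stored macro on an open dataset.

    ``overrides`` maps ``(step position, parameter index)`` to a replacement
    value; all other parameters replay with their recorded values. Every
    executed step is recorded as new history against ``id_file``; the
    original rows are immutable. Missing plugins and bad override indices
    fail before anything executes; a plugin failure mid-run leaves the steps
    already recorded in place (history is append-only).
    """
    items = macro_items(store, id_macro)
    sequence = [
        (
            it.id_action,
            it.action,
            [p.value for p in it.params],
            [p.hash for p in it.params],
        )
        for it in items
    ]
    return _execute_sequence(
        store, registry, plugins, sequence, dataset, int(id_file), overrides
    )


def replay_batch_text(
    store: ProvenanceStore,
    registry: OpenFilesRegistry,
    plugins: PluginRegistry,
    parsed: Sequence[ParsedAction],
    dataset,
    id_file: int,
    overrides: Mapping[tuple[int, int], object] | None = None,
) -> ReplayReport:
    """Replay actions parsed from an exported batch/macro text file.

    LOAD_FILE/SAVE entries (file events in a full history rendering) are
    skipped; every other action needs a registered plugin.
    """
    sequence = [
        (
            None,
            pa.action,
            [p.value for p in pa.params],
            [p.hash for p in pa.params],
        )
        for pa in parsed
        if pa.action not in RESERVED_ACTIONS
    ]
    if not sequence:
        raise ValidationError("batch text contains no replayable actions")
    return _execute_sequence(
        store, registry, plugins, sequence, dataset, int(id_file), overrides
    )
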