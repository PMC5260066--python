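"""Recording of processing actions — the plugin-facing provenance contract.

A processing routine describes what it just did as a :class:`ProvenanceEntry`
(its macro key, the ordered parameters with human-readable descriptions, and
for quantitation methods the result file). :func:`record_action` turns one
entry into the full relational footprint in a single atomic write: the
ACTIONS row, one PARAMS row per parameter (file-valued parameters are
ingested into hash-named managed storage), FILES_ACTIONS links to every
target file, and for quantitation the ingested result plus its RESULTS row.

Comments and the approved/not-approved flag live in the two comment tables
and drive the history filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .errors import StateError, ValidationError
from .file_registry import (
    RESERVED_ACTIONS,
    OpenFilesRegistry,
    _insert_action,
    _link_file_action,
    _maybe_text_history,
    ingest_managed_file,
)
from .schema_store import ProvenanceStore

MAX_ACTION_KEY_LEN = 64

ApprovalStatus = Literal["approved", "not-approved", "unset"]
CommentTarget = Literal["action", "result"]


@dataclass(frozen=True)
class ParamSpec:
    """One parameter of a processing action.

    ``value`` is stored as text — a number, free text, or (for
    ``is_file=True``) a file path whose content is hashed and archived.
    ``description`` must be non-empty: a comment with the units and/or
    meaning is always saved alongside the value.
    """

    value: str
    description: str
    is_file: bool = False

    def validate(self) -> None:
        if not str(self.description).strip():
            raise ValidationError("parameter description must be non-empty")


@dataclass
class ProvenanceEntry:
    """In-flight description of one performed action, handed to the recorder.

    Mirrors the carrier object a plugin fills after running: the action
    keyword, all parameters in order, and — iff the quantitation flag is
    set — the path of the result file it produced.
    """

    action: str
    params: list[ParamSpec] = field(default_factory=list)
    is_quantitation: bool = False
    result_path: str | Path | None = None
    result_description: str = "quantitation result"

    def validate(self) -> None:
        key = str(self.action)
        if not key.strip():
            raise ValidationError("action keyword must be non-empty")
        if len(key) > MAX_ACTION_KEY_LEN:
            raise ValidationError(
                f"action keyword exceeds {MAX_ACTION_KEY_LEN} characters: {key!r}"
            )
        if key in RESERVED_ACTIONS:
            raise ValidationError(f"action keyword {key!r} is reserved")
        for p in self.params:
            p.validate()
        if self.is_quantitation and self.result_path is None:
            raise ValidationError("quantitation entries require a result_path")
        if not self.is_quantitation and self.result_path is not None:
            raise ValidationError("result_path is only allowed for quantitation entries")


@dataclass(frozen=True)
class CommentRecord:
    id_action: int
    comment: str
    approved: str | None
    target: CommentTarget


def record_action(
    store: ProvenanceStore,
    registry: OpenFilesRegistry,
    entry: ProvenanceEntry,
    target_ids: Sequence[int],
) -> int:
    """Record one performed action against the given open files.

    Returns the new ``ID_action``. The write is atomic: a failing entry
    leaves every table's row count unchanged. All file content referenced
    by the entry is read before any row is written, so I/O errors cannot
    produce partial history.
    """
    entry.validate()
    if not target_ids:
        raise ValidationError("record_action requires at least one target file id")
    targets = [int(t) for t in target_ids]
    for t in targets:
        if not registry.is_open(t):
            raise StateError(f"target file {t} is not open")

    # read all referenced file content up front (fail before any write)
    param_payloads: list[bytes | None] = []
    for p in entry.params:
        param_payloads.append(Path(p.value).read_bytes() if p.is_file else None)
    result_payload: bytes | None = None
    if entry.is_quantitation:
        result_payload = Path(entry.result_path).read_bytes()

    with store.transaction():
        id_action = _insert_action(store, str(entry.action))
        for p, payload in zip(entry.params, param_payloads):
            if p.is_file:
                _, h = ingest_managed_file(store, payload, "parameter")
                value = str(Path(p.value).resolve())
            else:
                h = ""
                value = str(p.value)
            store.execute(
                "INSERT INTO PARAMS (ID_action, parameter, description, hash)"
                " VALUES (?, ?, ?, ?)",
                (id_action, value, str(p.description), h),
            )
        if entry.is_quantitation:
            _, rh = ingest_managed_file(store, result_payload, "result")
            store.execute(
                "INSERT INTO RESULTS (ID_action, parameter, description, hash)"
                " VALUES (?, ?, ?, ?)",
                (
                    id_action,
                    str(Path(entry.result_path).resolve()),
                    entry.result_description,
                    rh,
                ),
            )
        for t in targets:
            _link_file_action(store, t, id_action)

    for t in targets:
        _maybe_text_history(store, t, id_action)
    return id_action


def _comment_table(target: CommentTarget) -> str:
    if target == "action":
        return "ACTIONS_comment"
    if target == "result":
        return "RESULTS_comment"
    raise ValidationError(f"comment target must be 'action' or 'result', got {target!r}")


def _require_action(store: ProvenanceStore, id_action: int) -> None:
    if store.query_one(
        "SELECT 1 FROM ACTIONS WHERE ID_action = ?", (int(id_action),)
    ) is None:
        raise ValidationError(f"unknown action id {id_action}")


def add_comment(
    store: ProvenanceStore,
    id_action: int,
    text: str,
    target: CommentTarget = "action",
) -> CommentRecord:
    """Append a comment to an action or to the result it produced."""
    table = _comment_table(target)
    _require_action(store, id_action)
    if target == "result":
        if store.query_one(
            "SELECT 1 FROM RESULTS WHERE ID_action = ?", (int(id_action),)
        ) is None:
            raise ValidationError(f"action {id_action} produced no result to comment on")
    with store.transaction():
        store.execute(
            f"INSERT INTO {table} (ID_action, comment) VALUES (?, ?)",
            (int(id_action), str(text)),
        )
    return CommentRecord(int(id_action), str(text), None, target)


def set_approval(
    store: ProvenanceStore,
    id_action: int,
    status: ApprovalStatus,
    target: CommentTarget = "action",
) -> CommentRecord:
    """Mark an action approved / not-approved / unset (last write wins)."""
    if status not in ("approved", "not-approved", "unset"):
        raise ValidationError(f"invalid approval status {status!r}")
    table = _comment_table(target)
    _require_action(store, id_action)
    stored = None if status == "unset" else status
    with store.transaction():
        existing = store.query_one(
            f"SELECT COUNT(*) FROM {table} WHERE ID_action = ?", (int(id_action),)
        )[0]
        if existing:
            store.execute(
                f"UPDATE {table} SET approved = ? WHERE ID_action = ?",
                (stored, int(id_action)),
            )
        else:
            store.execute(
                f"INSERT INTO {table} (ID_action, comment, approved) VALUES (?, '', ?)",
                (int(id_action), stored),
            )
    return CommentRecord(int(id_action), "", stored, target)


def get_comments(
    store: ProvenanceStore, id_action: int, target: CommentTarget = "action"
) -> list[CommentRecord]:
    table = _comment_table(target)
    rows = store.query_all(
        f"SELECT ID_action, comment, approved FROM {table}"
        " WHERE ID_action = ? ORDER BY rowid",
        (int(id_action),),
    )
    return [CommentRecord(r["ID_action"], r["comment"], r["approved"], target) for r in rows]


def approval_status(
    store: ProvenanceStore, id_action: int, target: CommentTarget = "action"
) -> str:
    """Current approval state of an action: approved / not-approved / unset."""
    table = _comment_table(target)
    row = store.query_one(
        f"SELECT approved FROM {table} WHERE ID_action = ?"
        " AND approved IS NOT NULL ORDER BY rowid DESC LIMIT 1",
        (int(id_action),),
    )
    return row["approved"] if row is not None else "unset"


def filter_actions_by_approval(
    store: ProvenanceStore,
    status: str,
    target: CommentTarget = "action",
) -> list[int]:
    """Action ids matching an approval filter: 'all', 'approved' or 'not-approved'."""
    if status == "all":
        return [r["ID_action"] for r in store.query_all(
            "SELECT ID_action FROM ACTIONS ORDER BY ID_action"
        )]
    if status not in ("approved", "not-approved"):
        raise ValidationError(f"invalid approval filter {status!r}")
    table = _comment_table(target)
    rows = store.query_all(
        f"SELECT DISTINCT ID_action FROM {table} WHERE approved = ? ORDER BY ID_action",
        (status,),
    )
    return [r["ID_action"] for r in rows]
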