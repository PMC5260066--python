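"""Hash-based file identification and registration.

Every tracked data file is identified by the SHA-256 of its bytes, not by
its path, so a file moved elsewhere on disk is still recognized. Loading a
file whose content is already known returns the existing ``ID_file``
(deduplication); saving a processed file records a new row whose ``child``
column points at the file it was derived from, building the parent→child
lineage chain. The set of files currently open in a processing session is
kept in an in-memory registry that is never persisted.
"""

from __future__ import annotations

import hashlib
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import IntegrityError, StateError, ValidationError
from .schema_store import ProvenanceStore

HASH_RE = re.compile(r"^[0-9a-f]{64}$")

#: Action keywords written by the registry itself; plugins must not use them.
RESERVED_ACTIONS = ("LOAD_FILE", "SAVE")

#: child-column sentinel for a file with no recorded parent.
NO_PARENT = -1


@dataclass(frozen=True)
class FileRecord:
    """One row of FILES: a tracked data file and its lineage pointer."""

    id_file: int
    path: str
    hash: str
    child: int  # ID_file of the originating ("parent") file, or -1


def compute_file_hash(source: str | Path | bytes) -> str:
    """SHA-256 of a file's bytes (or of raw bytes), as 64 lowercase hex chars."""
    if isinstance(source, (bytes, bytearray)):
        data = bytes(source)
    else:
        data = Path(source).read_bytes()
    return hashlib.sha256(data).hexdigest()


def normalize_hash(value: str) -> str:
    """Lowercase and validate a hex digest; raise ValidationError if malformed."""
    h = str(value).strip().lower()
    if not HASH_RE.match(h):
        raise ValidationError(f"malformed SHA-256 hash: {value!r}")
    return h


class OpenFilesRegistry:
    """The in-memory "OPEN FILES" registry of a processing session.

    Maps each open ``ID_file`` to the id of the action that (re-)opened it,
    which defines the current-session boundary for history queries. Kept in
    insertion order, duplicate-free, and never written to disk.
    """

    def __init__(self) -> None:
        self._entries: dict[int, int] = {}

    @property
    def open_ids(self) -> tuple[int, ...]:
        return tuple(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, id_file: int) -> bool:
        return id_file in self._entries

    def is_open(self, id_file: int) -> bool:
        return id_file in self._entries

    def entry_action(self, id_file: int) -> int:
        """Id of the LOAD_FILE/SAVE action that last opened this file."""
        if id_file not in self._entries:
            raise StateError(f"file {id_file} is not open")
        return self._entries[id_file]

    def _enter(self, id_file: int, id_action: int) -> None:
        # re-entering moves the session boundary to the new action
        self._entries.pop(id_file, None)
        self._entries[id_file] = id_action

    def _remove(self, id_file: int) -> None:
        if id_file not in self._entries:
            raise StateError(f"file {id_file} is not open")
        del self._entries[id_file]


def close_file(registry: OpenFilesRegistry, id_file: int) -> OpenFilesRegistry:
    """Drop a file from the session registry; the database is untouched."""
    registry._remove(id_file)
    return registry


def file_record(store: ProvenanceStore, id_file: int) -> FileRecord:
    row = store.query_one(
        "SELECT ID_file, path, hash, child FROM FILES WHERE ID_file = ?",
        (int(id_file),),
    )
    if row is None:
        raise ValidationError(f"unknown file id {id_file}")
    return FileRecord(row["ID_file"], row["path"], row["hash"], row["child"])


def find_file_by_hash(store: ProvenanceStore, hash: str) -> FileRecord | None:
    """Exact content-hash lookup; hashes are normalized to lowercase first."""
    h = normalize_hash(hash)
    row = store.query_one(
        "SELECT ID_file, path, hash, child FROM FILES WHERE hash = ?", (h,)
    )
    if row is None:
        return None
    return FileRecord(row["ID_file"], row["path"], row["hash"], row["child"])


def lineage(store: ProvenanceStore, id_file: int) -> list[int]:
    """Derivation chain of a file as ids, root ancestor first, target last.

    Follows the ``child`` pointer (which names the file this one was derived
    from) until the -1 sentinel. Bounded by the FILES row count, so a
    corrupted cyclic chain raises instead of looping.
    """
    limit = store.row_count("FILES")
    chain: list[int] = []
    current = int(id_file)
    while current != NO_PARENT:
        if len(chain) > limit:
            raise IntegrityError(f"lineage of file {id_file} does not terminate")
        chain.append(current)
        current = file_record(store, current).child
    chain.reverse()
    return chain


def _insert_action(store: ProvenanceStore, action: str) -> int:
    cur = store.execute(
        "INSERT INTO ACTIONS (opertime, action) VALUES (?, ?)",
        (store.timestamp(), action),
    )
    return cur.lastrowid


def _link_file_action(store: ProvenanceStore, id_file: int, id_action: int) -> None:
    store.execute(
        "INSERT INTO FILES_ACTIONS (ID_file, ID_action) VALUES (?, ?)",
        (id_file, id_action),
    )


def register_loaded_file(
    store: ProvenanceStore, registry: OpenFilesRegistry, path: str | Path
) -> int:
    """Register a data file being loaded into the session.

    The file's hash is looked up in FILES: a known hash returns the existing
    ``ID_file`` (no new row, even if the path differs); an unknown hash gets
    a fresh row with ``child = -1``. Either way a ``LOAD_FILE`` action is
    recorded and linked, and the id enters the OPEN FILES registry.
    """
    path = Path(path)
    h = compute_file_hash(path)
    with store.transaction():
        existing = find_file_by_hash(store, h)
        if existing is not None:
            id_file = existing.id_file
        else:
            cur = store.execute(
                "INSERT INTO FILES (path, hash, child) VALUES (?, ?, ?)",
                (str(path.resolve()), h, NO_PARENT),
            )
            id_file = cur.lastrowid
        id_action = _insert_action(store, "LOAD_FILE")
        _link_file_action(store, id_file, id_action)
    registry._enter(id_file, id_action)
    _maybe_text_history(store, id_file, id_action)
    return id_file


def register_saved_file(
    store: ProvenanceStore,
    registry: OpenFilesRegistry,
    original_id: int,
    new_path: str | Path,
) -> int:
    """Register a processed file that the caller has just written to disk.

    The original (parent) file leaves the registry; the saved file gets a
    FILES row whose ``child`` column holds the parent's id, a ``SAVE``
    action linked to it, and takes the parent's place in the registry. If
    the saved bytes are identical to an already-registered file, that
    file's id is reused (content is identity) and only the SAVE event is
    appended.
    """
    if not registry.is_open(original_id):
        raise StateError(f"file {original_id} is not open; cannot register a save")
    new_path = Path(new_path)
    h = compute_file_hash(new_path)
    with store.transaction():
        existing = find_file_by_hash(store, h)
        if existing is not None:
            id_file = existing.id_file
        else:
            cur = store.execute(
                "INSERT INTO FILES (path, hash, child) VALUES (?, ?, ?)",
                (str(new_path.resolve()), h, int(original_id)),
            )
            id_file = cur.lastrowid
        id_action = _insert_action(store, "SAVE")
        _link_file_action(store, id_file, id_action)
    registry._remove(original_id)
    registry._enter(id_file, id_action)
    _maybe_text_history(store, id_file, id_action)
    return id_file


def ingest_managed_file(
    store: ProvenanceStore, source: str | Path | bytes, kind: str
) -> tuple[Path, str]:
    """Copy a parameter or result file into hash-named managed storage.

    The copy's basename is the SHA-256 of its content; re-ingesting the
    same bytes is a no-op returning the same stored path.
    """
    if kind == "parameter":
        dest_dir = store.layout.param_files_dir
    elif kind == "result":
        dest_dir = store.layout.results_dir
    else:
        raise ValidationError(f"kind must be 'parameter' or 'result', got {kind!r}")
    data = bytes(source) if isinstance(source, (bytes, bytearray)) else Path(source).read_bytes()
    h = hashlib.sha256(data).hexdigest()
    dest = dest_dir / h
    if not dest.exists():
        tmp = dest_dir / f".{h}.tmp.{os.getpid()}"
        tmp.write_bytes(data)
        tmp.replace(dest)
    return dest, h


def managed_file_path(store: ProvenanceStore, hash: str, kind: str) -> Path:
    """Path of a managed copy; raises IntegrityError if it is missing."""
    h = normalize_hash(hash)
    dest_dir = (
        store.layout.param_files_dir if kind == "parameter" else store.layout.results_dir
    )
    path = dest_dir / h
    if not path.exists():
        raise IntegrityError(f"managed {kind} file {h} is missing", hash=h)
    return path


def distinct_hash_count(hashes: Iterable[str]) -> int:
    """Number of distinct normalized hashes (dedup bookkeeping helper)."""
    return len({normalize_hash(h) for h in hashes})


def _maybe_text_history(store: ProvenanceStore, id_file: int, id_action: int) -> None:
    if not store.text_history:
        return
    from .history_query import append_text_history  # local import: layer above

    append_text_history(store, id_file, id_action)
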