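"""Provenance store: one embedded SQLite file plus hash-addressed file areas.

A store lives in a user-chosen directory and consists of

* ``spectratrack.db`` — the relational audit trail (nine tables),
* ``param_files/``   — ingested parameter files, renamed to the SHA-256 of
  their content,
* ``results/``       — ingested quantitation result files, same naming rule.

The schema is append-only by contract: the public API only ever inserts
rows (the single exception is the approval flag on the two comment tables,
which is explicitly last-write-wins). Identifiers are generated
incrementally and never reused.

Tables
------
Processing history (5): ``ACTIONS``, ``PARAMS``, ``RESULTS``, ``FILES``,
``FILES_ACTIONS``. Comments (2): ``ACTIONS_comment``, ``RESULTS_comment``.
Macros (2): ``MACRO``, ``MACRO_contents``.
"""

from __future__ import annotations

import datetime
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator

from .errors import SchemaError, StateError

DB_FILENAME = "spectratrack.db"
PARAM_FILES_DIRNAME = "param_files"
RESULTS_DIRNAME = "results"

#: DDL per table, in canonical creation order. Column order is part of the
#: public contract (see introspect_schema).
SCHEMA_DDL: dict[str, str] = {
    "ACTIONS": (
        "CREATE TABLE ACTIONS ("
        " ID_action INTEGER PRIMARY KEY,"
        " opertime TEXT NOT NULL,"
        " action VARCHAR(64) NOT NULL)"
    ),
    "PARAMS": (
        "CREATE TABLE PARAMS ("
        " ID INTEGER PRIMARY KEY,"
        " ID_action INTEGER NOT NULL REFERENCES ACTIONS(ID_action),"
        " parameter TEXT NOT NULL,"
        " description TEXT NOT NULL,"
        " hash TEXT NOT NULL DEFAULT '')"
    ),
    "RESULTS": (
        "CREATE TABLE RESULTS ("
        " ID INTEGER PRIMARY KEY,"
        " ID_action INTEGER NOT NULL REFERENCES ACTIONS(ID_action),"
        " parameter TEXT NOT NULL,"
        " description TEXT NOT NULL,"
        " hash TEXT NOT NULL)"
    ),
    "FILES": (
        "CREATE TABLE FILES ("
        " ID_file INTEGER PRIMARY KEY,"
        " path TEXT NOT NULL,"
        " hash TEXT NOT NULL UNIQUE,"
        " child INTEGER NOT NULL DEFAULT -1)"
    ),
    "FILES_ACTIONS": (
        "CREATE TABLE FILES_ACTIONS ("
        " ID INTEGER PRIMARY KEY,"
        " ID_file INTEGER NOT NULL REFERENCES FILES(ID_file),"
        " ID_action INTEGER NOT NULL REFERENCES ACTIONS(ID_action))"
    ),
    "MACRO": (
        "CREATE TABLE MACRO ("
        " ID_macro INTEGER PRIMARY KEY,"
        " name TEXT NOT NULL UNIQUE,"
        " comment TEXT NOT NULL DEFAULT '')"
    ),
    "MACRO_contents": (
        "CREATE TABLE MACRO_contents ("
        " ID_macro INTEGER NOT NULL REFERENCES MACRO(ID_macro),"
        " ID_action INTEGER NOT NULL REFERENCES ACTIONS(ID_action),"
        " position INTEGER NOT NULL,"
        " UNIQUE (ID_macro, position))"
    ),
    "ACTIONS_comment": (
        "CREATE TABLE ACTIONS_comment ("
        " ID_action INTEGER NOT NULL REFERENCES ACTIONS(ID_action),"
        " comment TEXT NOT NULL,"
        " approved TEXT)"
    ),
    "RESULTS_comment": (
        "CREATE TABLE RESULTS_comment ("
        " ID_action INTEGER NOT NULL REFERENCES ACTIONS(ID_action),"
        " comment TEXT NOT NULL,"
        " approved TEXT)"
    ),
}

#: Expected column names in order, derived once from the DDL above.
EXPECTED_COLUMNS: dict[str, tuple[str, ...]] = {
    "ACTIONS": ("ID_action", "opertime", "action"),
    "PARAMS": ("ID", "ID_action", "parameter", "description", "hash"),
    "RESULTS": ("ID", "ID_action", "parameter", "description", "hash"),
    "FILES": ("ID_file", "path", "hash", "child"),
    "FILES_ACTIONS": ("ID", "ID_file", "ID_action"),
    "MACRO": ("ID_macro", "name", "comment"),
    "MACRO_contents": ("ID_macro", "ID_action", "position"),
    "ACTIONS_comment": ("ID_action", "comment", "approved"),
    "RESULTS_comment": ("ID_action", "comment", "approved"),
}

HISTORY_TABLES = ("ACTIONS", "PARAMS", "RESULTS", "FILES", "FILES_ACTIONS")
COMMENT_TABLES = ("ACTIONS_comment", "RESULTS_comment")
MACRO_TABLES = ("MACRO", "MACRO_contents")


TIMESTAMP_FMT = "%Y-%m-%dT%H:%M:%SZ"


def utc_timestamp() -> str:
    """Current time as ISO 8601 UTC with second precision (``...Z``)."""
    return datetime.datetime.now(datetime.timezone.utc).strftime(TIMESTAMP_FMT)


def scripted_clock(start: str = "2020-01-01T00:00:00Z", step_s: int = 1) -> Callable[[], str]:
    """A deterministic clock: fixed start, advancing ``step_s`` per call.

    Used by scripted sessions whose entire on-disk output (including
    rendered timestamps) must be byte-reproducible.
    """
    t0 = datetime.datetime.strptime(start, TIMESTAMP_FMT)
    state = {"n": 0}

    def clock() -> str:
        stamp = t0 + datetime.timedelta(seconds=state["n"] * step_s)
        state["n"] += 1
        return stamp.strftime(TIMESTAMP_FMT)

    return clock


@dataclass(frozen=True)
class StoreLayout:
    """On-disk layout of one provenance store (Fig-1-style directory)."""

    root_dir: Path
    db_file: Path
    param_files_dir: Path
    results_dir: Path

    @classmethod
    def under(cls, root_dir: Path | str) -> "StoreLayout":
        root = Path(root_dir)
        return cls(
            root_dir=root,
            db_file=root / DB_FILENAME,
            param_files_dir=root / PARAM_FILES_DIRNAME,
            results_dir=root / RESULTS_DIRNAME,
        )


class ProvenanceStore:
    """An open provenance store: layout handle + live SQLite connection.

    Parameters
    ----------
    layout : StoreLayout
        Directory layout the store was opened from.
    connection : sqlite3.Connection
        Open connection in manual-transaction mode.
    text_history : bool
        When True, every recorded event is also appended as batch-format
        text to ``<data file>.history.txt`` next to the tracked data file
        (the optional plain-text history mirror).
    clock : callable returning str, optional
        Source of ``opertime`` timestamps; defaults to the UTC wall clock.
        Scripted sessions may inject a deterministic clock so that rendered
        histories (and hence bundle bytes) are exactly reproducible.
    """

    def __init__(
        self,
        layout: StoreLayout,
        connection: sqlite3.Connection,
        text_history: bool = False,
        clock: Callable[[], str] | None = None,
    ):
        self.layout = layout
        self._conn: sqlite3.Connection | None = connection
        self.text_history = text_history
        self.clock = clock or utc_timestamp
        self._in_tx = False

    def timestamp(self) -> str:
        return self.clock()

    # -- connection management -------------------------------------------

    @property
    def closed(self) -> bool:
        return self._conn is None

    @property
    def connection(self) -> sqlite3.Connection:
        if self._conn is None:
            raise StateError("provenance store is closed")
        return self._conn

    def close(self) -> None:
        if self._conn is not None:
            self._conn.close()
            self._conn = None

    def __enter__(self) -> "ProvenanceStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- SQL helpers ------------------------------------------------------

    def execute(self, sql: str, params: tuple = ()) -> sqlite3.Cursor:
        return self.connection.execute(sql, params)

    def query_one(self, sql: str, params: tuple = ()):
        return self.execute(sql, params).fetchone()

    def query_all(self, sql: str, params: tuple = ()) -> list:
        return self.execute(sql, params).fetchall()

    def row_count(self, table: str) -> int:
        if table not in EXPECTED_COLUMNS:
            raise SchemaError(f"unknown table {table!r}")
        return self.query_one(f"SELECT COUNT(*) FROM {table}")[0]

    def row_counts(self) -> dict[str, int]:
        """Row count per table, in canonical table order."""
        return {t: self.row_count(t) for t in SCHEMA_DDL}

    @contextmanager
    def transaction(self) -> Iterator[None]:
        """All-or-nothing write scope; nested scopes join the outer one."""
        if self._in_tx:
            yield
            return
        conn = self.connection
        conn.execute("BEGIN")
        self._in_tx = True
        try:
            yield
        except BaseException:
            conn.execute("ROLLBACK")
            raise
        else:
            conn.execute("COMMIT")
        finally:
            self._in_tx = False


def init_store(
    root_dir: Path | str,
    text_history: bool = False,
    clock: Callable[[], str] | None = None,
) -> ProvenanceStore:
    """Create a provenance store under ``root_dir``, or open an existing one.

    A fresh directory gets the database file with exactly the nine tables
    plus the two managed subdirectories. Calling this on a directory that
    already holds a valid store opens it without touching existing rows.

    Raises
    ------
    OSError
        ``root_dir`` (or its parent) is not writable / not a directory.
    SchemaError
        The directory contains a corrupt or foreign database file.
    """
    layout = StoreLayout.under(root_dir)
    layout.root_dir.mkdir(parents=True, exist_ok=True)
    existing = layout.db_file.exists()

    conn = sqlite3.connect(layout.db_file, isolation_level=None)
    conn.row_factory = sqlite3.Row
    try:
        conn.execute("PRAGMA foreign_keys = ON")
        if existing:
            _validate_schema(conn)
        else:
            with conn:
                for ddl in SCHEMA_DDL.values():
                    conn.execute(ddl)
    except BaseException:
        conn.close()
        raise

    layout.param_files_dir.mkdir(exist_ok=True)
    layout.results_dir.mkdir(exist_ok=True)
    return ProvenanceStore(layout, conn, text_history=text_history, clock=clock)


def open_store(
    root_dir: Path | str,
    text_history: bool = False,
    clock: Callable[[], str] | None = None,
) -> ProvenanceStore:
    """Open an existing store; unlike init_store, refuse to create one."""
    layout = StoreLayout.under(root_dir)
    if not layout.db_file.exists():
        raise SchemaError(f"no provenance store found under {layout.root_dir}")
    return init_store(root_dir, text_history=text_history, clock=clock)


def introspect_schema(store: ProvenanceStore) -> dict[str, tuple[str, ...]]:
    """Map every table name to its ordered column names.

    The result is stable (canonical table order, DDL column order) and,
    round-tripped through close/reopen, identical across runs.
    """
    if store.closed:
        raise SchemaError("cannot introspect a closed store")
    _validate_schema(store.connection)
    out: dict[str, tuple[str, ...]] = {}
    for table in SCHEMA_DDL:
        rows = store.query_all(f"PRAGMA table_info({table})")
        out[table] = tuple(r["name"] for r in rows)
    return out


def _validate_schema(conn: sqlite3.Connection) -> None:
    try:
        rows = conn.execute(
            "SELECT name FROM sqlite_master"
            " WHERE type = 'table' AND name NOT LIKE 'sqlite_%'"
        ).fetchall()
    except sqlite3.DatabaseError as exc:
        raise SchemaError(f"not a valid provenance database: {exc}") from exc
    names = {r[0] for r in rows}
    expected = set(SCHEMA_DDL)
    if names != expected:
        missing = sorted(expected - names)
        extra = sorted(names - expected)
        raise SchemaError(
            f"schema mismatch: missing tables {missing}, unexpected tables {extra}"
        )
    for table, cols in EXPECTED_COLUMNS.items():
        info = conn.execute(f"PRAGMA table_info({table})").fetchall()
        found = tuple(r[1] for r in info)
        if found != cols:
            raise SchemaError(
                f"table {table} has columns {found}, expected {cols}"
            )
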