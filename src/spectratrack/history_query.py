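"""History extraction: listings, lineage traversal, batch text, bundle export.

Three query paths mirror the history menu of the tracker:

* :func:`actions_for_file` — every action ever linked to one file, in the
  order the links were written (includes LOAD_FILE/SAVE events);
* :func:`history_with_parents` — the same, concatenated over the file's
  derivation chain, root ancestor first;
* :func:`session_actions` — only the current session (data mode), or the
  steps leading up to a quantitation (result mode).

Any listing renders to the deterministic ``processing.batch`` text dialect
(:func:`render_batch` / :func:`parse_batch`), and a quantitation result can
be exported as a self-contained reproducibility bundle: one zip holding the
original data file, the rendered history, every parameter file, the result
file and a manifest of content hashes (:func:`export_result_bundle`).
"""

from __future__ import annotations

import hashlib
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

from .errors import IntegrityError, ParseError, ValidationError
from .file_registry import (
    OpenFilesRegistry,
    compute_file_hash,
    file_record,
    lineage,
    managed_file_path,
    normalize_hash,
)
from .schema_store import ProvenanceStore

BATCH_HEADER = "# spectratrack batch v1"


class ParamEntry(NamedTuple):
    value: str
    description: str
    hash: str  # empty for non-file parameters


class ResultEntry(NamedTuple):
    name: str  # original full file name as recorded
    hash: str


@dataclass(frozen=True)
class HistoryItem:
    """One action as seen from a history listing: a faithful join of
    ACTIONS x PARAMS x RESULTS x the comment tables for a given file link."""

    id_action: int
    opertime: str
    action: str
    params: tuple[ParamEntry, ...]
    result: ResultEntry | None
    comments: tuple[str, ...]
    approved: str  # 'approved' | 'not-approved' | 'unset'
    id_file: int | None
    link_id: int | None


@dataclass(frozen=True)
class BundleEntry:
    name: str
    hash: str
    role: Literal["data", "batch", "parameter", "result"]


@dataclass(frozen=True)
class BundleManifest:
    entries: tuple[BundleEntry, ...]

    def by_role(self, role: str) -> tuple[BundleEntry, ...]:
        return tuple(e for e in self.entries if e.role == role)

    def hashes(self) -> set[str]:
        return {e.hash for e in self.entries}


@dataclass(frozen=True)
class VerifyReport:
    """Outcome of a managed-storage audit: files checked and mismatches found."""

    checked: int
    mismatched: tuple[tuple[str, str], ...]  # (hash or path, reason)

    @property
    def ok(self) -> bool:
        return not self.mismatched


# ---------------------------------------------------------------------------
# item construction


def item_for_action(
    store: ProvenanceStore,
    id_action: int,
    id_file: int | None = None,
    link_id: int | None = None,
) -> HistoryItem:
    """Assemble the full HistoryItem for one recorded action."""
    from .action_recorder import approval_status  # local import avoids cycle

    row = store.query_one(
        "SELECT ID_action, opertime, action FROM ACTIONS WHERE ID_action = ?",
        (int(id_action),),
    )
    if row is None:
        raise ValidationError(f"unknown action id {id_action}")
    params = tuple(
        ParamEntry(r["parameter"], r["description"], r["hash"])
        for r in store.query_all(
            "SELECT parameter, description, hash FROM PARAMS"
            " WHERE ID_action = ? ORDER BY ID",
            (int(id_action),),
        )
    )
    rrow = store.query_one(
        "SELECT parameter, hash FROM RESULTS WHERE ID_action = ? ORDER BY ID LIMIT 1",
        (int(id_action),),
    )
    result = ResultEntry(rrow["parameter"], rrow["hash"]) if rrow is not None else None
    comments = tuple(
        r["comment"]
        for r in store.query_all(
            "SELECT comment FROM ACTIONS_comment WHERE ID_action = ?"
            " AND comment != '' ORDER BY rowid",
            (int(id_action),),
        )
    )
    return HistoryItem(
        id_action=row["ID_action"],
        opertime=row["opertime"],
        action=row["action"],
        params=params,
        result=result,
        comments=comments,
        approved=approval_status(store, id_action),
        id_file=id_file,
        link_id=link_id,
    )


# ---------------------------------------------------------------------------
# listings


def actions_for_file(store: ProvenanceStore, id_file: int) -> list[HistoryItem]:
    """All actions linked to one file, in FILES_ACTIONS link order.

    Includes the LOAD_FILE and SAVE events, so this is the complete audit
    trail of what ever touched this file's content.
    """
    file_record(store, id_file)  # raises ValidationError for unknown ids
    rows = store.query_all(
        "SELECT ID, ID_action FROM FILES_ACTIONS WHERE ID_file = ? ORDER BY ID",
        (int(id_file),),
    )
    return [
        item_for_action(store, r["ID_action"], id_file=int(id_file), link_id=r["ID"])
        for r in rows
    ]


def history_with_parents(store: ProvenanceStore, id_file: int) -> list[HistoryItem]:
    """Actions over the whole derivation chain, root ancestor first.

    ``actions_for_file(root)`` is always a prefix of the output, and the
    total length is the sum of the per-ancestor listings.
    """
    items: list[HistoryItem] = []
    for ancestor in lineage(store, id_file):
        items.extend(actions_for_file(store, ancestor))
    return items


def session_actions(
    store: ProvenanceStore,
    registry: OpenFilesRegistry | None,
    key: int | str,
    mode: Literal["data", "result"] = "data",
) -> list[HistoryItem]:
    """Current-session listing.

    data mode
        ``key`` is an open ``ID_file``; returns the actions linked to it
        since it last entered the OPEN FILES registry (the opening
        LOAD_FILE/SAVE event included).
    result mode
        ``key`` is a result-file hash; returns the producing file's history
        truncated at — and including — the quantitation action, i.e. all
        steps that led to that result.
    """
    if mode == "data":
        if registry is None:
            raise ValidationError("data-mode session queries require the registry")
        id_file = int(key)
        entry_action = registry.entry_action(id_file)  # StateError if not open
        return [
            it for it in actions_for_file(store, id_file) if it.id_action >= entry_action
        ]
    if mode == "result":
        id_action, id_file = resolve_result(store, str(key))
        items = []
        for it in actions_for_file(store, id_file):
            items.append(it)
            if it.id_action == id_action:
                break
        return items
    raise ValidationError(f"mode must be 'data' or 'result', got {mode!r}")


def resolve_result(store: ProvenanceStore, result_hash: str) -> tuple[int, int]:
    """Map a result hash to (producing ID_action, the ID_file it was applied to)."""
    h = normalize_hash(result_hash)
    row = store.query_one(
        "SELECT ID_action FROM RESULTS WHERE hash = ? ORDER BY ID LIMIT 1", (h,)
    )
    if row is None:
        raise ValidationError(f"no recorded result with hash {h}")
    id_action = row["ID_action"]
    link = store.query_one(
        "SELECT ID_file FROM FILES_ACTIONS WHERE ID_action = ? ORDER BY ID LIMIT 1",
        (id_action,),
    )
    if link is None:
        raise IntegrityError(f"result action {id_action} is linked to no file")
    return id_action, link["ID_file"]


# ---------------------------------------------------------------------------
# batch text


def render_batch(items: Sequence[HistoryItem]) -> str:
    """Render history items as deterministic batch text.

    One ``ACTION <key> <timestamp>`` line per item, one
    ``PARAM <description> = <value>`` line per parameter (file parameters
    carry a ``HASH <64-hex>`` suffix), and a ``RESULT <basename> HASH ...``
    line for quantitation items. UTF-8, ``\\n`` endings, byte-identical for
    identical inputs. File-valued parameters are rendered by basename: the
    hash, not the recording machine's absolute path, is the portable
    identity of the file.
    """
    if not items:
        raise ValidationError("cannot render an empty history")
    lines = [BATCH_HEADER]
    for it in items:
        lines.append(f"ACTION {it.action} {it.opertime}")
        for p in it.params:
            if p.hash:
                line = f"PARAM {p.description} = {Path(p.value).name} HASH {p.hash}"
            else:
                line = f"PARAM {p.description} = {p.value}"
            lines.append(line)
        if it.result is not None:
            lines.append(f"RESULT {Path(it.result.name).name} HASH {it.result.hash}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ParsedAction:
    action: str
    opertime: str
    params: tuple[ParamEntry, ...]
    result: ResultEntry | None


def parse_batch(text: str) -> list[ParsedAction]:
    """Parse batch text back into per-action records (render round-trip).

    The ``PARAM`` separator is the last `` = `` on the line, so descriptions
    may contain `` = `` but values must not.
    """
    lines = text.splitlines()
    if not lines or lines[0].strip() != BATCH_HEADER:
        raise ParseError(f"missing batch header {BATCH_HEADER!r}", line=1)
    actions: list[ParsedAction] = []
    current: dict | None = None

    def flush():
        nonlocal current
        if current is not None:
            actions.append(
                ParsedAction(
                    current["action"],
                    current["opertime"],
                    tuple(current["params"]),
                    current["result"],
                )
            )
            current = None

    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("ACTION "):
            flush()
            parts = line.split(" ", 2)
            if len(parts) != 3:
                raise ParseError("ACTION line needs a key and a timestamp", line=lineno)
            current = {"action": parts[1], "opertime": parts[2], "params": [], "result": None}
        elif line.startswith("PARAM "):
            if current is None:
                raise ParseError("PARAM before any ACTION", line=lineno)
            body = line[len("PARAM "):]
            h = ""
            if " HASH " in body:
                body, h = body.rsplit(" HASH ", 1)
                h = normalize_hash(h)
            if " = " not in body:
                raise ParseError("PARAM line lacks ' = ' separator", line=lineno)
            desc, value = body.rsplit(" = ", 1)
            current["params"].append(ParamEntry(value, desc, h))
        elif line.startswith("RESULT "):
            if current is None:
                raise ParseError("RESULT before any ACTION", line=lineno)
            body = line[len("RESULT "):]
            if " HASH " not in body:
                raise ParseError("RESULT line lacks a HASH", line=lineno)
            name, h = body.rsplit(" HASH ", 1)
            current["result"] = ResultEntry(name, normalize_hash(h))
        else:
            raise ParseError(f"unrecognized batch line: {line!r}", line=lineno)
    flush()
    return actions


# ---------------------------------------------------------------------------
# per-file text history mirror


def append_text_history(store: ProvenanceStore, id_file: int, id_action: int) -> None:
    """Append one action's batch lines to ``<data file>.history.txt``.

    The optional plain-text mirror of the database history, written next to
    the tracked data file. The header line is written once per file.
    """
    rec = file_record(store, id_file)
    target = Path(rec.path + ".history.txt")
    block = render_batch([item_for_action(store, id_action, id_file=id_file)])
    body = block[len(BATCH_HEADER) + 1 :]  # strip "header\n"
    if target.exists():
        with target.open("a", encoding="utf-8") as fh:
            fh.write(body)
    else:
        target.write_text(block, encoding="utf-8")


# ---------------------------------------------------------------------------
# bundle export


def export_result_bundle(
    store: ProvenanceStore, result_hash: str, out_path: str | Path
) -> BundleManifest:
    """Export everything needed to reproduce one quantitation as a zip.

    Contents: the originating data file (root ancestor of the lineage), a
    ``processing.batch`` rendering of the history with parents truncated at
    the quantitation, every file-valued parameter of those actions, the
    result file, and a ``MANIFEST.txt`` mapping archive names to content
    hashes and roles. Files are archived under their original basenames;
    name collisions are disambiguated with an 8-char hash prefix.
    """
    h = normalize_hash(result_hash)
    id_action, id_file = resolve_result(store, h)

    chain = lineage(store, id_file)
    root = file_record(store, chain[0])

    items: list[HistoryItem] = []
    for it in history_with_parents(store, id_file):
        items.append(it)
        if it.id_action == id_action:
            break

    root_path = Path(root.path)
    if not root_path.exists():
        raise IntegrityError(
            f"original data file {root.path} (hash {root.hash}) is missing",
            hash=root.hash,
        )
    data_bytes = root_path.read_bytes()
    data_hash = hashlib.sha256(data_bytes).hexdigest()
    if data_hash != root.hash:
        raise IntegrityError(
            f"data file {root.path} no longer matches its recorded hash {root.hash}",
            hash=root.hash,
        )

    batch_text = render_batch(items).encode("utf-8")
    batch_hash = hashlib.sha256(batch_text).hexdigest()

    # file-valued parameters of the exported actions, deduplicated by hash
    param_files: dict[str, tuple[str, bytes]] = {}
    for it in items:
        for p in it.params:
            if p.hash and p.hash not in param_files:
                src = managed_file_path(store, p.hash, "parameter")
                param_files[p.hash] = (Path(p.value).name, src.read_bytes())

    result_row = store.query_one(
        "SELECT parameter FROM RESULTS WHERE hash = ? ORDER BY ID LIMIT 1", (h,)
    )
    result_src = managed_file_path(store, h, "result")
    result_name = Path(result_row["parameter"]).name
    result_bytes = result_src.read_bytes()

    used_names: set[str] = set()

    def unique_name(name: str, content_hash: str) -> str:
        final = name if name not in used_names else f"{content_hash[:8]}_{name}"
        used_names.add(final)
        return final

    members: list[tuple[str, bytes, str, str]] = []  # name, bytes, hash, role
    members.append((unique_name(root_path.name, data_hash), data_bytes, data_hash, "data"))
    members.append((unique_name("processing.batch", batch_hash), batch_text, batch_hash, "batch"))
    for phash, (pname, pbytes) in param_files.items():
        members.append((unique_name(pname, phash), pbytes, phash, "parameter"))
    members.append((unique_name(result_name, h), result_bytes, h, "result"))

    manifest = BundleManifest(
        tuple(BundleEntry(n, hh, role) for n, _, hh, role in members)
    )
    manifest_text = (
        "".join(f"{e.name}\t{e.hash}\t{e.role}\n" for e in manifest.entries)
    ).encode("utf-8")

    out_path = Path(out_path)
    with zipfile.ZipFile(out_path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, content, _, _ in members:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, content)
        info = zipfile.ZipInfo("MANIFEST.txt", date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, manifest_text)
    return manifest


# ---------------------------------------------------------------------------
# store verification


def verify_store(store: ProvenanceStore) -> VerifyReport:
    """Audit managed storage against the content-addressing guarantee.

    Recomputes the SHA-256 of every file in the two managed directories
    (its basename must equal the digest) and checks that every hash
    referenced from PARAMS and RESULTS has a managed copy on disk.
    """
    checked = 0
    mismatched: list[tuple[str, str]] = []
    for kind, directory in (
        ("parameter", store.layout.param_files_dir),
        ("result", store.layout.results_dir),
    ):
        for path in sorted(directory.iterdir()):
            if not path.is_file() or path.name.startswith("."):
                continue
            checked += 1
            actual = compute_file_hash(path)
            if actual != path.name:
                mismatched.append(
                    (path.name, f"{kind} file content hashes to {actual}")
                )
    for table, kind in (("PARAMS", "parameter"), ("RESULTS", "result")):
        directory = (
            store.layout.param_files_dir if kind == "parameter" else store.layout.results_dir
        )
        rows = store.query_all(
            f"SELECT DISTINCT hash FROM {table} WHERE hash != ''"
        )
        for r in rows:
            checked += 1
            if not (directory / r["hash"]).exists():
                mismatched.append((r["hash"], f"referenced {kind} file is missing"))
    return VerifyReport(checked, tuple(mismatched))
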