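"""History extraction: listings, lineage traversal, batch text, bundles, audit."""

import zipfile

import pytest

from spectratrack import (
    OpenFilesRegistry,
    ParamSpec,
    ProvenanceEntry,
    ValidationError,
    actions_for_file,
    close_file,
    compute_file_hash,
    export_result_bundle,
    history_with_parents,
    init_store,
    parse_batch,
    record_action,
    register_loaded_file,
    register_saved_file,
    render_batch,
    session_actions,
    verify_store,
)


def record_scale(store, registry, id_file, factor=2.0):
    return record_action(
        store, registry,
        ProvenanceEntry("SCALE", [ParamSpec(repr(factor), "scaling factor")]),
        [id_file],
    )


class TestActionsForFile:
    def test_load_two_ops_save_in_order(self, store, registry, make_file):
        id1 = register_loaded_file(store, registry, make_file("a.fid", b"v0"))
        record_scale(store, registry, id1, 2.0)
        record_scale(store, registry, id1, 3.0)
        register_saved_file(store, registry, id1, make_file("a1.fid", b"v1"))
        items = actions_for_file(store, id1)
        assert [it.action for it in items] == ["LOAD_FILE", "SCALE", "SCALE"]
        # the SAVE event is linked to the saved child, not the parent
        items2 = actions_for_file(store, 2)
        assert [it.action for it in items2] == ["SAVE"]

    def test_untouched_file_lists_only_its_load(self, store, registry, make_file):
        id1 = register_loaded_file(store, registry, make_file("a.fid", b"v0"))
        items = actions_for_file(store, id1)
        assert len(items) == 1 and items[0].action == "LOAD_FILE"

    def test_unknown_file_rejected(self, store):
        with pytest.raises(ValidationError):
            actions_for_file(store, 42)


def build_chain(store, registry, make_file, depth, ops_per_file=2):
    """Build a load/process/save chain and an oracle of expected action ids.

    The oracle replays the insertion rules by arithmetic alone: every event
    (load, op, save) takes the next global action id, and each file's
    history is the ids of the events linked to it.
    """
    next_action = store.row_count("ACTIONS")
    expected: dict[int, list[tuple[int, str]]] = {}
    ids = []

    id_file = register_loaded_file(store, registry, make_file("chain0.fid", b"c0"))
    next_action += 1
    expected[id_file] = [(next_action, "LOAD_FILE")]
    ids.append(id_file)
    for step in range(depth):
        for k in range(ops_per_file):
            record_scale(store, registry, ids[-1], 1.5 + step + 0.1 * k)
            next_action += 1
            expected[ids[-1]].append((next_action, "SCALE"))
        new_id = register_saved_file(
            store, registry, ids[-1], make_file(f"chain{step + 1}.fid", f"c{step + 1}")
        )
        next_action += 1
        expected[new_id] = [(next_action, "SAVE")]
        ids.append(new_id)
    return ids, expected


class TestHistoryWithParents:
    @pytest.mark.parametrize("depth", [1, 2, 5, 10])
    def test_matches_concatenated_oracle(self, tmp_path, make_file, depth):
        store = init_store(tmp_path / f"store{depth}")
        registry = OpenFilesRegistry()
        try:
            ids, expected = build_chain(store, registry, make_file, depth)
            target = ids[-1]
            items = history_with_parents(store, target)
            oracle = [pair for fid in ids for pair in expected[fid]]
            assert [(it.id_action, it.action) for it in items] == oracle
            # lengths are additive over the lineage
            assert len(items) == sum(
                len(actions_for_file(store, fid)) for fid in ids
            )
        finally:
            store.close()

    def test_root_history_is_a_prefix(self, store, registry, make_file):
        ids, _ = build_chain(store, registry, make_file, 3)
        items = history_with_parents(store, ids[-1])
        root_items = actions_for_file(store, ids[0])
        assert [it.id_action for it in items[: len(root_items)]] == [
            it.id_action for it in root_items
        ]

    def test_parentless_file_equals_plain_listing(self, store, registry, make_file):
        id1 = register_loaded_file(store, registry, make_file("a.fid", b"x"))
        record_scale(store, registry, id1)
        assert [it.id_action for it in history_with_parents(store, id1)] == [
            it.id_action for it in actions_for_file(store, id1)
        ]


class TestSessionActions:
    def test_data_mode_counts_ops_since_open(self, store, registry, make_file):
        id1 = register_loaded_file(store, registry, make_file("a.fid", b"x"))
        for _ in range(3):
            record_scale(store, registry, id1)
        items = session_actions(store, registry, id1, "data")
        # the opening LOAD_FILE event is part of the session
        assert [it.action for it in items] == ["LOAD_FILE"] + ["SCALE"] * 3

    def test_reopening_resets_the_session_boundary(self, store, registry, make_file):
        path = make_file("a.fid", b"x")
        id1 = register_loaded_file(store, registry, path)
        record_scale(store, registry, id1)
        close_file(registry, id1)
        register_loaded_file(store, registry, path)  # same content, same id
        record_scale(store, registry, id1)
        items = session_actions(store, registry, id1, "data")
        assert [it.action for it in items] == ["LOAD_FILE", "SCALE"]
        # full history still holds everything
        assert len(actions_for_file(store, id1)) == 4

    def test_result_mode_ends_at_the_quantitation(self, demo):
        store = init_store(demo["store_dir"])
        try:
            items = session_actions(store, None, demo["result_hash"], "result")
            assert [it.action for it in items] == [
                "LOAD_FILE", "APODIZE", "PHASE0", "QUANTIFY",
            ]
            assert items[-1].result is not None
            assert items[-1].result.hash == demo["result_hash"]
        finally:
            store.close()

    def test_unopened_file_is_an_error(self, store, registry, make_file):
        id1 = register_loaded_file(store, registry, make_file("a.fid", b"x"))
        close_file(registry, id1)
        with pytest.raises(Exception):
            session_actions(store, registry, id1, "data")


class TestBatchText:
    def test_render_parse_round_trip(self, store, registry, make_file):
        id1 = register_loaded_file(store, registry, make_file("a.fid", b"x"))
        record_scale(store, registry, id1, 2.5)
        basis = make_file("basis.ml", b"NAA\t0\t5\n")
        options = make_file("q.op", b"ZeroOrderPhase_deg: 0\n")
        result = make_file("r.results", b"NAA\t1.0\n")
        record_action(
            store, registry,
            ProvenanceEntry(
                "QUANTIFY",
                [
                    ParamSpec(str(basis), "Metabolite list file = ?", is_file=True),
                    ParamSpec(str(options), "Overall phases file = ?", is_file=True),
                ],
                is_quantitation=True,
                result_path=result,
            ),
            [id1],
        )
        items = actions_for_file(store, id1)
        text = render_batch(items)
        assert text == render_batch(items)  # byte-determinism
        parsed = parse_batch(text)
        assert [(p.action, p.opertime) for p in parsed] == [
            (it.action, it.opertime) for it in items
        ]
        from pathlib import Path

        for p, it in zip(parsed, items):
            # file params render by basename (the hash is the portable identity)
            assert [(e.value, e.description, e.hash) for e in p.params] == [
                (Path(e.value).name if e.hash else e.value, e.description, e.hash)
                for e in it.params
            ]
        assert parsed[-1].result.hash == items[-1].result.hash

    def test_file_params_carry_hash_suffix(self, store, registry, make_file):
        id1 = register_loaded_file(store, registry, make_file("a.fid", b"x"))
        basis = make_file("basis.ml", b"NAA\t0\t5\n")
        record_action(
            store, registry,
            ProvenanceEntry("CAL", [ParamSpec(str(basis), "basis", is_file=True)]),
            [id1],
        )
        text = render_batch(actions_for_file(store, id1))
        param_lines = [l for l in text.splitlines() if l.startswith("PARAM")]
        assert len(param_lines) == 1
        assert f" HASH {compute_file_hash(basis)}" in param_lines[0]

    def test_empty_history_rejected(self):
        with pytest.raises(ValidationError):
            render_batch([])


class TestBundleExport:
    def test_demo_bundle_covers_all_roles(self, demo, tmp_path):
        manifest = demo["manifest"]
        roles = [e.role for e in manifest.entries]
        assert roles.count("data") == 1
        assert roles.count("batch") == 1
        assert roles.count("result") == 1
        assert roles.count("parameter") == 2
        names = {e.name for e in manifest.entries}
        assert {"data.fid", "processing.batch", "basis.ml", "quant.op"} <= names
        with zipfile.ZipFile(demo["bundle_path"]) as zf:
            members = set(zf.namelist())
            assert names | {"MANIFEST.txt"} == members
            for e in manifest.entries:
                assert compute_file_hash(zf.read(e.name)) == e.hash

    def test_no_dangling_parameter_references(self, demo):
        """Every hash the exported actions reference appears in the manifest."""
        store = init_store(demo["store_dir"])
        try:
            items = session_actions(store, None, demo["result_hash"], "result")
            referenced = {p.hash for it in items for p in it.params if p.hash}
            referenced |= {it.result.hash for it in items if it.result}
        finally:
            store.close()
        assert referenced <= demo["manifest"].hashes()

    def test_reexport_is_deterministic(self, demo, tmp_path):
        store = init_store(demo["store_dir"])
        try:
            again = export_result_bundle(
                store, demo["result_hash"], tmp_path / "again.zip"
            )
        finally:
            store.close()
        assert again == demo["manifest"]

    def test_unknown_result_rejected(self, store):
        with pytest.raises(ValidationError):
            export_result_bundle(store, "0" * 64, "out.zip")


class TestVerifyStore:
    def test_pristine_store_is_clean(self, demo):
        store = init_store(demo["store_dir"])
        try:
            report = verify_store(store)
        finally:
            store.close()
        assert report.ok and report.checked > 0

    def test_empty_store_reports_zero(self, store):
        report = verify_store(store)
        assert (report.checked, len(report.mismatched)) == (0, 0)

    def test_single_byte_flip_detected(self, store, registry, make_file):
        id1 = register_loaded_file(store, registry, make_file("a.fid", b"x"))
        basis = make_file("basis.ml", b"NAA\t0\t5\n")
        record_action(
            store, registry,
            ProvenanceEntry("CAL", [ParamSpec(str(basis), "basis", is_file=True)]),
            [id1],
        )
        victim = next(store.layout.param_files_dir.iterdir())
        data = bytearray(victim.read_bytes())
        data[0] ^= 0xFF
        victim.write_bytes(bytes(data))
        report = verify_store(store)
        assert len(report.mismatched) == 1
        assert report.mismatched[0][0] == victim.name
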