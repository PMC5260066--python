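import pytest

from spectratrack import OpenFilesRegistry, init_store, run_demo_session


@pytest.fixture
def store(tmp_path):
    """A fresh provenance store in a temp directory, closed on teardown."""
    s = init_store(tmp_path / "store")
    yield s
    s.close()


@pytest.fixture
def registry():
    return OpenFilesRegistry()


@pytest.fixture
def make_file(tmp_path):
    """Write bytes (or text) under a given name and return the path."""

    def _make(name, content=b"payload"):
        path = tmp_path / name
        path.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(content, str):
            content = content.encode()
        path.write_bytes(content)
        return path

    return _make


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """One shared end-to-end demo session (store + work dirs kept on disk)."""
    base = tmp_path_factory.mktemp("demo")
    return run_demo_session(base / "store", base / "work", seed=1234)
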