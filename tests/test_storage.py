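"""Storage backends: listing, mkdir/delete, streaming copy contracts."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, strategies as st

from benchwork.errors import ConfigurationError, NotFoundError, TransferError
from benchwork.storage import (
    CHUNK_CEILING,
    InstrumentedBackend,
    LocalFsBackend,
    MemBackend,
    StorageRouter,
    default_router,
)
from benchwork.uris import UriRef


@pytest.fixture
def router(tmp_path):
    r = StorageRouter()
    r.register("file", LocalFsBackend("/"), backend_id="localfs")
    r.register("mem", MemBackend(), backend_id="memdata")
    return r


def _u(text):
    return UriRef.parse(text)


# -- listing -------------------------------------------------------------


def test_localfs_listing_sorted(router, tmp_path):
    (tmp_path / "b.txt").write_text("b")
    (tmp_path / "a.txt").write_text("a")
    (tmp_path / "sub").mkdir()
    listing = router.list_dir(_u(f"file://{tmp_path}"))
    assert listing.names() == ["a.txt", "b.txt", "sub"]
    assert listing.files() == ["a.txt", "b.txt"]


def test_empty_dir_lists_empty(router, tmp_path):
    d = tmp_path / "empty"
    d.mkdir()
    assert router.list_dir(_u(f"file://{d}")).entries == []


def test_missing_dir_not_found(router, tmp_path):
    with pytest.raises(NotFoundError):
        router.list_dir(_u(f"file://{tmp_path}/nope"))


def test_mem_listing_matches_manifest(router):
    names = [f"f{i}.fa" for i in range(5)]
    for n in names:
        router.write_bytes(_u(f"mem://box/data/{n}"), n.encode())
    listing = router.list_dir(_u("mem://box/data"))
    assert listing.files() == sorted(names)
    for entry in listing.entries:
        assert entry.size == len(entry.name)


# -- mkdir / delete ------------------------------------------------------


@pytest.mark.parametrize("scheme_base", ["mem://box", "file://{tmp}"])
def test_mkdir_recursive_then_delete_round_trip(router, tmp_path, scheme_base):
    base = scheme_base.format(tmp=tmp_path)
    before = router.list_dir(_u(base)).names() if router.exists(_u(base)) else []
    router.mkdir(_u(f"{base}/a/b/c"))
    assert router.is_dir(_u(f"{base}/a/b/c"))
    assert "b" in router.list_dir(_u(f"{base}/a")).names()
    router.delete(_u(f"{base}/a"), recursive=True)
    after = router.list_dir(_u(base)).names() if router.exists(_u(base)) else []
    assert after == before  # back to prior state


def test_delete_missing_not_found(router):
    with pytest.raises(NotFoundError):
        router.delete(_u("mem://box/nope.txt"))


def test_delete_nonempty_dir_requires_recursive(router):
    router.write_bytes(_u("mem://box/d/x"), b"x")
    with pytest.raises(TransferError):
        router.delete(_u("mem://box/d"))
    router.delete(_u("mem://box/d"), recursive=True)
    assert not router.exists(_u("mem://box/d"))


def test_mkdir_over_file_is_error(router):
    router.write_bytes(_u("mem://box/taken"), b"x")
    with pytest.raises(TransferError):
        router.mkdir(_u("mem://box/taken"))


# -- copy ----------------------------------------------------------------


def test_copy_zero_byte_file(router):
    router.write_bytes(_u("mem://box/empty"), b"")
    report = router.copy(_u("mem://box/empty"), _u("mem://box/empty2"))
    assert report.nbytes == 0
    assert report.sha256 == hashlib.sha256(b"").hexdigest()
    assert router.read_bytes(_u("mem://box/empty2")) == b""


def test_copy_onto_itself_rejected(router):
    router.write_bytes(_u("mem://box/x"), b"x")
    with pytest.raises(TransferError):
        router.copy(_u("mem://box/x"), _u("mem://box/x"))


def test_copy_overwrites_existing_destination(router):
    router.write_bytes(_u("mem://box/src"), b"new content")
    router.write_bytes(_u("mem://box/dst"), b"old")
    router.copy(_u("mem://box/src"), _u("mem://box/dst"))
    assert router.read_bytes(_u("mem://box/dst")) == b"new content"


@pytest.mark.parametrize("src_kind", ["mem", "file"])
@pytest.mark.parametrize("dst_kind", ["mem", "file"])
@pytest.mark.parametrize("size", [0, 1, 4096, 1_000_000])
def test_copy_checksum_preserving_matrix(router, tmp_path, src_kind, dst_kind, size):
    rng = np.random.default_rng(size + 1)
    payload = rng.bytes(size)
    src = _u(f"mem://box/in/p{size}") if src_kind == "mem" else _u(f"file://{tmp_path}/in_p{size}")
    dst = _u(f"mem://box/out/p{size}") if dst_kind == "mem" else _u(f"file://{tmp_path}/out_p{size}")
    router.write_bytes(src, payload)
    report = router.copy(src, dst)
    assert report.nbytes == size
    assert report.sha256 == hashlib.sha256(payload).hexdigest()
    assert router.read_bytes(dst) == payload


def test_streaming_bounded_buffer_and_no_spool(tmp_path):
    """100 MiB seeded payload: byte-identical, peak in-flight <= ceiling,
    and no file appears anywhere except the destination."""
    src_be = InstrumentedBackend(MemBackend())
    dst_be = InstrumentedBackend(MemBackend())
    router = StorageRouter()
    router.register("src", src_be)
    router.register("dst", dst_be)
    watched = tmp_path / "watched"
    watched.mkdir()
    router.register("file", LocalFsBackend(watched), backend_id="watched")

    size = 100 * 1024 * 1024
    payload = np.random.default_rng(42).bytes(size)
    src_be.inner._files.setdefault("box", {})["/big.bin"] = (payload, 0.0)

    snapshot_before = set(watched.rglob("*"))
    report = router.copy(_u("src://box/big.bin"), _u("dst://box/big.bin"))
    snapshot_after = set(watched.rglob("*"))

    assert report.nbytes == size
    assert report.sha256 == hashlib.sha256(payload).hexdigest()
    assert dst_be.inner._files["box"]["/big.bin"][0] == payload
    assert report.peak_buffered <= CHUNK_CEILING
    assert src_be.peak_chunk <= CHUNK_CEILING
    assert dst_be.peak_chunk <= CHUNK_CEILING
    assert snapshot_after == snapshot_before  # no spool files on disk


def test_chunk_ceiling_enforced(router):
    router.write_bytes(_u("mem://box/x"), b"x")
    with pytest.raises(TransferError):
        router.copy(_u("mem://box/x"), _u("mem://box/y"), chunk_size=CHUNK_CEILING + 1)


def test_copy_failure_cleans_partial_destination(router):
    class FlakyBackend(MemBackend):
        def open_read(self, uri, chunk_size):
            yield b"partial"
            raise NotFoundError("source vanished mid-copy")

    router.register("flaky", FlakyBackend())
    with pytest.raises(NotFoundError):
        router.copy(_u("flaky://box/x"), _u("mem://box/partial"))
    assert not router.exists(_u("mem://box/partial"))


# -- URI round trip and dispatch ----------------------------------------


@given(
    store=st.sampled_from(["box", "lab"]),
    parts=st.lists(
        st.text(alphabet="abc0189._-", min_size=1, max_size=6).filter(
            lambda s: s not in (".", "..")
        ),
        min_size=1,
        max_size=3,
    ),
    payload=st.binary(max_size=200),
)
def test_mem_write_read_round_trip(store, parts, payload):
    router = default_router()
    uri = UriRef(scheme="mem", host=store, path="/" + "/".join(parts))
    router.write_bytes(uri, payload)
    assert router.read_bytes(UriRef.parse(uri.render())) == payload


def test_unregistered_scheme_is_configuration_error(router):
    with pytest.raises(ConfigurationError):
        router.list_dir(_u("gridftp://host/x"))


def test_new_scheme_registers_without_touching_other_modules(router):
    """Pure scheme dispatch: a new mock backend slots in via register() only."""

    class UpperBackend(MemBackend):
        def open_read(self, uri, chunk_size):
            for chunk in super().open_read(uri, chunk_size):
                yield chunk.upper()

    router.register("shout", UpperBackend())
    router.write_bytes(_u("shout://box/x"), b"quiet")
    assert router.read_bytes(_u("shout://box/x")) == b"QUIET"
    assert "shout" in router.schemes()
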