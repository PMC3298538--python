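"""Data services: scheme-dispatched file operations and streaming copy.

Every operation takes a :class:`~benchwork.uris.UriRef`; the router picks
the backend registered for the URI's scheme.  Two backends are bundled:

* ``file://`` — the local filesystem (optionally rooted under a directory);
* ``mem://``  — in-memory named stores (``mem://store/path``), used for
  hermetic tests and as the substrate for instrumented backends.

Copy always *streams*: the producer reads bounded chunks which the consumer
writes immediately, so at no point is more than one chunk (default 4 MiB,
never more than the 8 MiB ceiling) buffered in flight, and no intermediate
spool file is ever created.  The transfer report records byte count, SHA-256
digest and the observed peak in-flight buffer so the contract is checkable.
"""

from __future__ import annotations

import hashlib
import shutil
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator

from .errors import (
    BackendUnreachable,
    ConfigurationError,
    NotFoundError,
    TransferError,
)
from .uris import UriRef

DEFAULT_CHUNK = 4 * 1024 * 1024
CHUNK_CEILING = 8 * 1024 * 1024


@dataclass(frozen=True)
class DirEntry:
    name: str
    kind: str  # "file" | "dir"
    size: int
    mtime: float


@dataclass
class DirListing:
    entries: list[DirEntry]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        assert len(names) == len(set(names)), "duplicate names in listing"
        self.entries = sorted(self.entries, key=lambda e: e.name)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def files(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "file"]


@dataclass
class TransferReport:
    src: str
    dst: str
    nbytes: int
    sha256: str
    peak_buffered: int
    duration: float


class StorageBackend:
    """Contract every storage driver implements.

    Paths handed to a backend are the URI path (absolute, normalized) plus
    the URI host where the scheme uses it (``mem``).  A driver that cannot
    support an operation raises ``NotImplementedError`` and must declare so
    via ``capabilities``.
    """

    capabilities = frozenset({"list", "read", "write", "delete", "mkdir"})

    def listing(self, uri: UriRef) -> DirListing:
        raise NotImplementedError

    def exists(self, uri: UriRef) -> bool:
        raise NotImplementedError

    def is_dir(self, uri: UriRef) -> bool:
        raise NotImplementedError

    def open_read(self, uri: UriRef, chunk_size: int) -> Iterator[bytes]:
        raise NotImplementedError

    def open_write(self, uri: UriRef):
        """Return a writer object with ``write(bytes)``, ``close()``, ``abort()``."""
        raise NotImplementedError

    def delete(self, uri: UriRef, recursive: bool = False) -> None:
        raise NotImplementedError

    def mkdir(self, uri: UriRef) -> None:
        raise NotImplementedError


# ---------------------------------------------------------------------------


class LocalFsBackend(StorageBackend):
    """Local filesystem driver; URI paths map under an optional root."""

    def __init__(self, root: str | Path = "/"):
        self.root = Path(root)

    def _fs(self, uri: UriRef) -> Path:
        rel = uri.path.lstrip("/")
        return (self.root / rel) if rel else self.root

    def listing(self, uri: UriRef) -> DirListing:
        p = self._fs(uri)
        if not p.exists():
            raise NotFoundError(f"no such directory: {uri.render()}")
        if not p.is_dir():
            raise NotFoundError(f"not a directory: {uri.render()}")
        entries = []
        for child in p.iterdir():
            st = child.stat()
            entries.append(
                DirEntry(
                    name=child.name,
                    kind="dir" if child.is_dir() else "file",
                    size=st.st_size if child.is_file() else 0,
                    mtime=st.st_mtime,
                )
            )
        return DirListing(entries)

    def exists(self, uri: UriRef) -> bool:
        return self._fs(uri).exists()

    def is_dir(self, uri: UriRef) -> bool:
        return self._fs(uri).is_dir()

    def open_read(self, uri: UriRef, chunk_size: int) -> Iterator[bytes]:
        p = self._fs(uri)
        if not p.is_file():
            raise NotFoundError(f"no such file: {uri.render()}")
        with open(p, "rb") as fh:
            while True:
                chunk = fh.read(chunk_size)
                if not chunk:
                    return
                yield chunk

    def open_write(self, uri: UriRef):
        p = self._fs(uri)
        p.parent.mkdir(parents=True, exist_ok=True)
        return _LocalWriter(p)

    def delete(self, uri: UriRef, recursive: bool = False) -> None:
        p = self._fs(uri)
        if not p.exists():
            raise NotFoundError(f"no such path: {uri.render()}")
        if p.is_dir():
            if recursive:
                shutil.rmtree(p)
            else:
                try:
                    p.rmdir()
                except OSError:
                    raise TransferError(
                        f"directory not empty (use recursive): {uri.render()}"
                    )
        else:
            p.unlink()

    def mkdir(self, uri: UriRef) -> None:
        p = self._fs(uri)
        if p.is_file():
            raise TransferError(f"mkdir over existing file: {uri.render()}")
        p.mkdir(parents=True, exist_ok=True)


class _LocalWriter:
    def __init__(self, path: Path):
        self.path = path
        self._fh = open(path, "wb")

    def write(self, chunk: bytes) -> None:
        self._fh.write(chunk)

    def close(self) -> None:
        self._fh.close()

    def abort(self) -> None:
        self._fh.close()
        try:
            self.path.unlink()
        except FileNotFoundError:
            pass


# ---------------------------------------------------------------------------


class MemBackend(StorageBackend):
    """In-memory named stores: ``mem://<store>/<path>``.

    ``reachable`` models a mock network partition: when False, every
    operation raises :class:`BackendUnreachable` (a *blocked*, not error,
    condition for the engine).
    """

    def __init__(self, reachable: bool = True):
        # store name -> {path: (bytes, mtime)}
        self._files: dict[str, dict[str, tuple[bytes, float]]] = {}
        self._dirs: dict[str, set[str]] = {}
        self.reachable = reachable

    def _check(self):
        if not self.reachable:
            raise BackendUnreachable("mem backend configured unreachable")

    def _store(self, uri: UriRef):
        name = uri.host or "default"
        return self._files.setdefault(name, {}), self._dirs.setdefault(name, {"/"})

    @staticmethod
    def _parents(path: str) -> list[str]:
        parts = [p for p in path.split("/") if p]
        return ["/" + "/".join(parts[:i]) for i in range(1, len(parts))]

    def listing(self, uri: UriRef) -> DirListing:
        self._check()
        files, dirs = self._store(uri)
        base = uri.path.rstrip("/") or "/"
        if base != "/" and base not in dirs and not self._implicit_dir(files, base):
            raise NotFoundError(f"no such directory: {uri.render()}")
        prefix = base if base.endswith("/") else base + "/"
        entries: dict[str, DirEntry] = {}
        for path, (data, mtime) in files.items():
            if path.startswith(prefix):
                rest = path[len(prefix):]
                if "/" in rest:
                    name = rest.split("/", 1)[0]
                    entries.setdefault(name, DirEntry(name, "dir", 0, mtime))
                else:
                    entries[rest] = DirEntry(rest, "file", len(data), mtime)
        for d in dirs:
            if d.startswith(prefix):
                rest = d[len(prefix):]
                if rest and "/" not in rest:
                    entries.setdefault(rest, DirEntry(rest, "dir", 0, 0.0))
        return DirListing(list(entries.values()))

    @staticmethod
    def _implicit_dir(files: dict, base: str) -> bool:
        prefix = base + "/"
        return any(p.startswith(prefix) for p in files)

    def exists(self, uri: UriRef) -> bool:
        self._check()
        files, dirs = self._store(uri)
        p = uri.path.rstrip("/") or "/"
        return p in files or p in dirs or self._implicit_dir(files, p)

    def is_dir(self, uri: UriRef) -> bool:
        self._check()
        files, dirs = self._store(uri)
        p = uri.path.rstrip("/") or "/"
        return p in dirs or self._implicit_dir(files, p)

    def open_read(self, uri: UriRef, chunk_size: int) -> Iterator[bytes]:
        self._check()
        files, _ = self._store(uri)
        if uri.path not in files:
            raise NotFoundError(f"no such file: {uri.render()}")
        data = files[uri.path][0]
        for off in range(0, len(data), chunk_size):
            yield data[off : off + chunk_size]

    def open_write(self, uri: UriRef):
        self._check()
        files, dirs = self._store(uri)
        for parent in self._parents(uri.path):
            dirs.add(parent)
        return _MemWriter(files, uri.path)

    def delete(self, uri: UriRef, recursive: bool = False) -> None:
        self._check()
        files, dirs = self._store(uri)
        p = uri.path.rstrip("/") or "/"
        if p in files:
            del files[p]
            return
        if p in dirs or self._implicit_dir(files, p):
            children = [f for f in files if f.startswith(p + "/")]
            subdirs = [d for d in dirs if d.startswith(p + "/")]
            if (children or subdirs) and not recursive:
                raise TransferError(f"directory not empty (use recursive): {uri.render()}")
            for f in children:
                del files[f]
            for d in subdirs:
                dirs.discard(d)
            dirs.discard(p)
            return
        raise NotFoundError(f"no such path: {uri.render()}")

    def mkdir(self, uri: UriRef) -> None:
        self._check()
        files, dirs = self._store(uri)
        p = uri.path.rstrip("/") or "/"
        if p in files:
            raise TransferError(f"mkdir over existing file: {uri.render()}")
        for parent in self._parents(p):
            dirs.add(parent)
        dirs.add(p)


class _MemWriter:
    def __init__(self, files: dict, path: str):
        self._files = files
        self._path = path
        self._buf = bytearray()
        self._open = True

    def write(self, chunk: bytes) -> None:
        self._buf.extend(chunk)

    def close(self) -> None:
        self._files[self._path] = (bytes(self._buf), time.time())
        self._open = False

    def abort(self) -> None:
        self._buf.clear()
        self._open = False


# ---------------------------------------------------------------------------


class InstrumentedBackend(StorageBackend):
    """Wrapper that accounts for every chunk crossing it.

    Used as the oracle for the streaming contract: ``peak_chunk`` is the
    largest single buffer seen in flight, ``bytes_read``/``bytes_written``
    the totals.
    """

    def __init__(self, inner: StorageBackend):
        self.inner = inner
        self.peak_chunk = 0
        self.bytes_read = 0
        self.bytes_written = 0

    def listing(self, uri):
        return self.inner.listing(uri)

    def exists(self, uri):
        return self.inner.exists(uri)

    def is_dir(self, uri):
        return self.inner.is_dir(uri)

    def open_read(self, uri, chunk_size):
        for chunk in self.inner.open_read(uri, chunk_size):
            self.peak_chunk = max(self.peak_chunk, len(chunk))
            self.bytes_read += len(chunk)
            yield chunk

    def open_write(self, uri):
        writer = self.inner.open_write(uri)
        outer = self

        class _W:
            def write(self, chunk):
                outer.peak_chunk = max(outer.peak_chunk, len(chunk))
                outer.bytes_written += len(chunk)
                writer.write(chunk)

            def close(self):
                writer.close()

            def abort(self):
                writer.abort()

        return _W()

    def delete(self, uri, recursive=False):
        return self.inner.delete(uri, recursive=recursive)

    def mkdir(self, uri):
        return self.inner.mkdir(uri)


# ---------------------------------------------------------------------------


@dataclass
class _Registration:
    backend: StorageBackend
    backend_id: str
    requires_credential: bool = False


class StorageRouter:
    """Dispatches URI operations to the backend registered for the scheme.

    An optional ``credential_resolver`` (callable ``backend_id -> secret``)
    is consulted before touching a backend registered with
    ``requires_credential=True``; if it raises
    :class:`~benchwork.errors.Blocked` the operation never starts.
    Registering a new scheme requires no change anywhere else.
    """

    def __init__(self, credential_resolver: Callable[[str], bytes] | None = None):
        self._by_scheme: dict[str, _Registration] = {}
        self.credential_resolver = credential_resolver

    def register(
        self,
        scheme: str,
        backend: StorageBackend,
        backend_id: str | None = None,
        requires_credential: bool = False,
    ) -> None:
        self._by_scheme[scheme] = _Registration(
            backend=backend,
            backend_id=backend_id or scheme,
            requires_credential=requires_credential,
        )

    def schemes(self) -> list[str]:
        return sorted(self._by_scheme)

    def _resolve(self, uri: UriRef) -> StorageBackend:
        reg = self._by_scheme.get(uri.scheme)
        if reg is None:
            raise ConfigurationError(f"no storage backend for scheme {uri.scheme!r}")
        if reg.requires_credential and self.credential_resolver is not None:
            self.credential_resolver(reg.backend_id)  # may raise Blocked
        return reg.backend

    # -- operations ---------------------------------------------------
    def list_dir(self, uri: UriRef) -> DirListing:
        return self._resolve(uri).listing(uri)

    def exists(self, uri: UriRef) -> bool:
        return self._resolve(uri).exists(uri)

    def is_dir(self, uri: UriRef) -> bool:
        return self._resolve(uri).is_dir(uri)

    def delete(self, uri: UriRef, recursive: bool = False) -> None:
        self._resolve(uri).delete(uri, recursive=recursive)

    def mkdir(self, uri: UriRef) -> None:
        self._resolve(uri).mkdir(uri)

    def read_bytes(self, uri: UriRef) -> bytes:
        return b"".join(self._resolve(uri).open_read(uri, DEFAULT_CHUNK))

    def write_bytes(self, uri: UriRef, data: bytes) -> None:
        w = self._resolve(uri).open_write(uri)
        try:
            w.write(data)
        except Exception:
            w.abort()
            raise
        w.close()

    def copy(
        self,
        src: UriRef,
        dst: UriRef,
        chunk_size: int = DEFAULT_CHUNK,
    ) -> TransferReport:
        """Stream *src* to *dst* with a bounded in-flight buffer.

        Overwrites an existing destination file (stage-out must be
        re-runnable after resume).  A copy onto the very same location is
        rejected.  On a mid-copy source failure the partial destination is
        cleaned up.
        """
        if src.same_location(dst):
            raise TransferError(f"refusing to copy {src.render()} onto itself")
        if chunk_size <= 0 or chunk_size > CHUNK_CEILING:
            raise TransferError(
                f"chunk_size {chunk_size} outside (0, {CHUNK_CEILING}]"
            )
        src_be = self._resolve(src)
        dst_be = self._resolve(dst)
        digest = hashlib.sha256()
        nbytes = 0
        peak = 0
        started = time.monotonic()
        writer = dst_be.open_write(dst)
        try:
            for chunk in src_be.open_read(src, chunk_size):
                peak = max(peak, len(chunk))
                digest.update(chunk)
                nbytes += len(chunk)
                writer.write(chunk)
        except Exception:
            writer.abort()
            raise
        writer.close()
        return TransferReport(
            src=src.render(),
            dst=dst.render(),
            nbytes=nbytes,
            sha256=digest.hexdigest(),
            peak_buffered=peak,
            duration=time.monotonic() - started,
        )

    def rename(self, src: UriRef, dst: UriRef) -> TransferReport:
        # No rename primitive in the backend contract; realized as copy+delete.
        report = self.copy(src, dst)
        self.delete(src)
        return report

    def checksum(self, uri: UriRef, chunk_size: int = DEFAULT_CHUNK) -> str:
        digest = hashlib.sha256()
        for chunk in self._resolve(uri).open_read(uri, chunk_size):
            digest.update(chunk)
        return digest.hexdigest()


def default_router(credential_resolver=None) -> StorageRouter:
    """Router with the bundled ``file://`` and ``mem://`` backends."""
    router = StorageRouter(credential_resolver=credential_resolver)
    router.register("file", LocalFsBackend("/"), backend_id="localfs")
    router.register("mem", MemBackend(), backend_id="memdata")
    return router
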