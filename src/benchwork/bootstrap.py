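"""Assemble a working engine from a registry config.

Wires the bundled storage drivers (``file``, ``mem``) and compute backends
(``localexec``, ``mockq``) to whatever the registry declares, opens the
store under a home directory, and returns a ready :class:`Engine`.  Both
the CLI and the test harness go through this one path; custom drivers can
be injected for new schemes without touching any other module.
"""

from __future__ import annotations

from pathlib import Path

from .compute import ComputeBackend, ComputeRegistry, LocalExecBackend, MockQueueBackend
from .credentials import DEFAULT_KDF_ITERATIONS, CredentialVault
from .engine import Engine
from .errors import ConfigurationError
from .persistence import Store
from .registry import Registry, load_registry
from .storage import LocalFsBackend, MemBackend, StorageBackend, StorageRouter


def build_engine(
    home: str | Path,
    registry: Registry | str | Path | dict,
    storage_drivers: dict[str, StorageBackend] | None = None,
    compute_backends: dict[str, ComputeBackend] | None = None,
    task_env: dict[str, str] | None = None,
    checkpoint=None,
    kdf_iterations: int = DEFAULT_KDF_ITERATIONS,
    lease_ttl: float = 60.0,
) -> Engine:
    """Build an engine rooted at *home* (created if missing).

    *storage_drivers* / *compute_backends* override or extend the bundled
    implementations, keyed by URI scheme.
    """
    home = Path(home).resolve()  # scratch paths must not depend on cwd
    home.mkdir(parents=True, exist_ok=True)
    if not isinstance(registry, Registry):
        registry = load_registry(registry)

    store = Store(home / "state.db")
    vault = CredentialVault(store, kdf_iterations=kdf_iterations)

    drivers: dict[str, StorageBackend] = {
        "file": LocalFsBackend("/"),
        "mem": MemBackend(),
    }
    drivers.update(storage_drivers or {})
    computes: dict[str, ComputeBackend] = {
        "localexec": LocalExecBackend(),
        "mockq": MockQueueBackend(),
    }
    computes.update(compute_backends or {})

    router = StorageRouter()
    compute = ComputeRegistry()
    for descriptor in registry.backends.values():
        if descriptor.kind == "storage":
            driver = drivers.get(descriptor.scheme)
            if driver is None:
                raise ConfigurationError(
                    f"no storage driver for scheme {descriptor.scheme!r}"
                    f" (backend {descriptor.id!r})"
                )
            if isinstance(driver, MemBackend) and not descriptor.reachable:
                driver.reachable = False
            router.register(
                descriptor.scheme,
                driver,
                backend_id=descriptor.id,
                requires_credential=descriptor.requires_credential,
            )
        else:
            backend = computes.get(descriptor.scheme)
            if backend is None:
                raise ConfigurationError(
                    f"no compute driver for scheme {descriptor.scheme!r}"
                    f" (backend {descriptor.id!r})"
                )
            if isinstance(backend, MockQueueBackend) and not descriptor.reachable:
                backend.reachable = False
            compute.register(descriptor.id, backend)

    return Engine(
        registry=registry,
        store=store,
        storage=router,
        compute=compute,
        vault=vault,
        work_root=home / "work",
        task_env=task_env,
        checkpoint=checkpoint,
        lease_ttl=lease_ttl,
    )
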