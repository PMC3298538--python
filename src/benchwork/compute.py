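"""Execution services: pluggable compute backends and the task lifecycle.

A compute backend exposes only ``submit / poll / cancel``; scheduling
itself belongs to the external resource, never to the engine.  Two backends
are bundled:

* ``localexec`` — direct subprocess execution on the local machine;
* ``mockq``     — a simulated batch queue (configurable dispatch latency,
  reachability and failure injection) standing in for cluster schedulers.

The task runner drives each leased task through
stage-in -> execute -> monitor -> stage-out -> cleanup, persisting a stage
marker after every completed stage so a resumed task restarts the last
incomplete stage and never re-runs a completed one — in particular a
command whose exit status has been recorded is never executed a second
time.  Transient faults (missing credential, unreachable backend, lost
submission after retries) put the task in the resumable *blocked* state;
only a nonzero exit code is a real *error* (the POSIX convention: success
iff exit status 0), and errors are deterministic so they are not retried.
"""

from __future__ import annotations

import fnmatch
import os
import shutil
import subprocess
import time
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .errors import BackendUnreachable, Blocked, ConfigurationError, NotFoundError
from .model import Status, Task
from .uris import UriRef

MAX_ATTEMPTS = 3  # transient-fault retries before blocking


@dataclass
class ExecSpec:
    argv: list[str]
    cwd: str
    env: dict[str, str] = field(default_factory=dict)
    stdout_path: str = ""
    stderr_path: str = ""


@dataclass
class PollResult:
    state: str  # queued | running | done | lost
    exit_code: int | None = None


@dataclass
class ExecutionResult:
    exit_code: int
    stdout_ref: UriRef
    stderr_ref: UriRef
    duration: float


class ComputeBackend:
    """Contract: ``submit`` returns an opaque handle unique per attempt;
    ``poll`` after *done* keeps returning *done* with the same exit code."""

    id: str = "abstract"

    def submit(self, spec: ExecSpec) -> str:
        raise NotImplementedError

    def poll(self, handle: str) -> PollResult:
        raise NotImplementedError

    def cancel(self, handle: str) -> None:
        raise NotImplementedError


class LocalExecBackend(ComputeBackend):
    """Runs the command as a direct subprocess; never through a shell."""

    id = "localexec"

    def __init__(self):
        self._procs: dict[str, subprocess.Popen] = {}
        self._done: dict[str, int] = {}

    def submit(self, spec: ExecSpec) -> str:
        handle = "local-" + uuid.uuid4().hex[:10]
        stdout = open(spec.stdout_path, "wb") if spec.stdout_path else subprocess.DEVNULL
        stderr = open(spec.stderr_path, "wb") if spec.stderr_path else subprocess.DEVNULL
        env = dict(os.environ)
        env.update(spec.env)
        try:
            proc = subprocess.Popen(
                spec.argv, cwd=spec.cwd, env=env, stdout=stdout, stderr=stderr
            )
        finally:
            for fh in (stdout, stderr):
                if hasattr(fh, "close"):
                    fh.close()
        self._procs[handle] = proc
        return handle

    def poll(self, handle: str) -> PollResult:
        if handle in self._done:
            return PollResult("done", self._done[handle])
        proc = self._procs.get(handle)
        if proc is None:
            return PollResult("lost")
        code = proc.poll()
        if code is None:
            return PollResult("running")
        self._done[handle] = code
        del self._procs[handle]
        return PollResult("done", code)

    def cancel(self, handle: str) -> None:
        proc = self._procs.get(handle)
        if proc is not None:
            proc.kill()


class MockQueueBackend(ComputeBackend):
    """Simulated batch queue.

    Jobs sit *queued* for ``latency_polls`` polls before being executed
    (synchronously, through the same no-shell subprocess path).  Fault
    injection: ``reachable=False`` makes ``submit`` raise
    :class:`BackendUnreachable` (a blocked condition); ``lose_next=n``
    makes the next *n* submissions report *lost* so retry policies can be
    exercised.
    """

    id = "mockq"

    def __init__(self, latency_polls: int = 1, reachable: bool = True):
        self.latency_polls = latency_polls
        self.reachable = reachable
        self.lose_next = 0
        self._queue: dict[str, tuple[ExecSpec, int]] = {}
        self._done: dict[str, int] = {}
        self._lost: set[str] = set()

    def submit(self, spec: ExecSpec) -> str:
        if not self.reachable:
            raise BackendUnreachable(f"compute backend {self.id!r} unreachable")
        handle = "mockq-" + uuid.uuid4().hex[:10]
        if self.lose_next > 0:
            self.lose_next -= 1
            self._lost.add(handle)
            return handle
        self._queue[handle] = (spec, self.latency_polls)
        return handle

    def poll(self, handle: str) -> PollResult:
        if handle in self._done:
            return PollResult("done", self._done[handle])
        if handle in self._lost:
            return PollResult("lost")
        entry = self._queue.get(handle)
        if entry is None:
            return PollResult("lost")
        spec, remaining = entry
        if remaining > 0:
            self._queue[handle] = (spec, remaining - 1)
            return PollResult("queued")
        env = dict(os.environ)
        env.update(spec.env)
        with open(spec.stdout_path or os.devnull, "wb") as out, open(
            spec.stderr_path or os.devnull, "wb"
        ) as err:
            proc = subprocess.run(spec.argv, cwd=spec.cwd, env=env, stdout=out, stderr=err)
        self._done[handle] = proc.returncode
        del self._queue[handle]
        return PollResult("done", proc.returncode)

    def cancel(self, handle: str) -> None:
        self._queue.pop(handle, None)


class ComputeRegistry:
    """Backend plug-ins by id; adding one requires no engine change."""

    def __init__(self):
        self._backends: dict[str, ComputeBackend] = {}

    def register(self, backend_id: str, backend: ComputeBackend) -> None:
        self._backends[backend_id] = backend

    def get(self, backend_id: str) -> ComputeBackend:
        try:
            return self._backends[backend_id]
        except KeyError:
            raise ConfigurationError(f"no compute backend registered as {backend_id!r}")

    def ids(self) -> list[str]:
        return sorted(self._backends)


# ---------------------------------------------------------------------------


class TaskRunner:
    """Drives one leased task through its lifecycle.

    Collaborators are injected: the persistence store (status/stage/syslog),
    the storage router (stage-in/out), the compute registry, a credential
    resolver, and a ``checkpoint`` hook used by crash-recovery tests to
    interrupt execution at persisted stage boundaries.
    """

    def __init__(
        self,
        store,
        storage,
        compute: ComputeRegistry,
        registry,
        work_root: str | Path,
        task_env: dict[str, str] | None = None,
        credential_getter: Callable[[str, str], bytes] | None = None,
        checkpoint: Callable[[str], None] | None = None,
        poll_interval: float = 0.01,
        retry_backoff: float = 0.05,
        clock=time,
    ):
        self.store = store
        self.storage = storage
        self.compute = compute
        self.registry = registry
        self.work_root = Path(work_root)
        self.task_env = dict(task_env or {})
        self.credential_getter = credential_getter
        self.checkpoint = checkpoint or (lambda name: None)
        self.poll_interval = poll_interval
        self.retry_backoff = retry_backoff
        self.clock = clock

    # -- helpers ------------------------------------------------------
    def _scratch(self, task: Task) -> Path:
        return self.work_root / task.workflow_id / task.id

    def _log(self, task: Task, message: str) -> None:
        self.store.append_syslog(task.id, message)

    def _require_credential(self, user: str, backend_id: str) -> None:
        descriptor = self.registry.backends.get(backend_id)
        if descriptor is None or not descriptor.requires_credential:
            return
        if self.credential_getter is None:
            raise Blocked(f"credential required for backend {backend_id!r}")
        self.credential_getter(user, backend_id)  # raises CredentialMissing

    def _block(self, task: Task, reason: str) -> None:
        self.store.set_task_status(task.id, Status.BLOCKED, blocked_reason=reason)
        self._log(task, f"blocked: {reason}")

    def _fail(self, task: Task, reason: str) -> None:
        self.store.set_task_status(task.id, Status.ERROR)
        self._log(task, f"error: {reason}")

    # -- lifecycle ----------------------------------------------------
    def run_task(self, task: Task, user: str, exec_backend_id: str) -> None:
        """Execute one task; all outcomes are surfaced as task states."""
        scratch = self._scratch(task)
        try:
            self._run_stages(task, user, exec_backend_id, scratch)
        except Blocked as exc:
            self._block(task, exc.reason)
        except NotFoundError as exc:
            # an input vanished between dependency resolution and stage-in:
            # transient from the engine's point of view, so blocked not error
            self._block(task, f"input unavailable: {exc}")

    def _run_stages(self, task: Task, user: str, exec_backend_id: str, scratch: Path) -> None:
        in_dir = scratch / "in"
        out_dir = scratch / "out"
        log_dir = scratch / "log"

        if task.status == Status.BLOCKED:
            self.store.set_task_status(task.id, Status.READY)
            task = self.store.task(task.id)

        # --- stage in -------------------------------------------------
        if task.stage == "new":
            self.store.set_task_status(task.id, Status.STAGING_IN)
            for d in (in_dir, out_dir, log_dir):
                d.mkdir(parents=True, exist_ok=True)
            self.store.set_task_scratch(task.id, str(scratch))
            self._log(task, f"scratch created at {scratch}")
            self._require_credential(user, exec_backend_id)
            for src_text, staged_name in task.stage_in:
                src = UriRef.parse(src_text)
                storage_be = self.registry.backend_for_scheme(src.scheme, kind="storage")
                if storage_be is not None:
                    self._require_credential(user, storage_be.id)
                dst = UriRef.parse(f"file://{in_dir / staged_name}")
                report = self.storage.copy(src, dst)
                self._log(
                    task,
                    f"staged in {src_text} -> {staged_name}"
                    f" ({report.nbytes} bytes, sha256 {report.sha256[:12]})",
                )
            self.store.set_task_stage(task.id, "staged_in")
            self.checkpoint("task.staged_in")
        else:
            # resumed mid-lifecycle: re-enter the pipeline where we left off
            self.store.set_task_status(task.id, Status.STAGING_IN)
            for d in (in_dir, out_dir, log_dir):
                d.mkdir(parents=True, exist_ok=True)

        # --- execute / monitor ---------------------------------------
        self.store.set_task_status(task.id, Status.RUNNING)
        if task.stage != "staged_in":
            task = self.store.task(task.id)
        if task.stage == "staged_in":
            backend = self.compute.get(exec_backend_id)
            spec = ExecSpec(
                argv=task.command,
                cwd=str(out_dir),
                env={
                    **self.task_env,
                    "BW_TASK": task.id,
                    "BW_JOB": task.job_id,
                    "BW_WORKFLOW": task.workflow_id,
                },
                stdout_path=str(log_dir / "stdout.txt"),
                stderr_path=str(log_dir / "stderr.txt"),
            )
            exit_code = self._execute_with_retries(task, backend, spec)
            self.store.set_task_stage(task.id, "executed", exit_code=exit_code)
            self._log(task, f"command finished with exit code {exit_code}")
            self.checkpoint("task.executed")
            task = self.store.task(task.id)

        # --- stage out / error ----------------------------------------
        if task.stage == "executed":
            if task.exit_code != 0:
                # deterministic failure: keep scratch for diagnosis, surface
                # the captured streams in the syslog area
                self._log(
                    task,
                    f"nonzero exit {task.exit_code}; scratch preserved at {scratch};"
                    f" stdout={log_dir / 'stdout.txt'} stderr={log_dir / 'stderr.txt'}",
                )
                stderr_tail = _tail(log_dir / "stderr.txt")
                if stderr_tail:
                    self._log(task, f"stderr: {stderr_tail}")
                self._fail(task, f"exit code {task.exit_code}")
                return
            self.store.set_task_status(task.id, Status.STAGING_OUT)
            dst_root = UriRef.parse(task.stage_out["dst"])
            storage_be = self.registry.backend_for_scheme(dst_root.scheme, kind="storage")
            if storage_be is not None:
                if not storage_be.reachable:
                    raise BackendUnreachable(
                        f"stage-out backend {storage_be.id!r} unreachable"
                    )
                self._require_credential(user, storage_be.id)
            self.storage.mkdir(dst_root)
            produces = task.stage_out.get("produces", [])
            staged = 0
            for name in sorted(p.name for p in out_dir.iterdir() if p.is_file()):
                if produces and not any(
                    fnmatch.fnmatchcase(name, pat) for pat in produces
                ):
                    continue
                src = UriRef.parse(f"file://{out_dir / name}")
                report = self.storage.copy(src, dst_root.join(name))
                self.store.record_transfer(
                    task.id, dst_root.join(name).render(), report.sha256, report.nbytes
                )
                staged += 1
            self._log(task, f"staged out {staged} file(s) to {dst_root.render()}")
            self.store.set_task_stage(task.id, "staged_out")
            self.checkpoint("task.staged_out")
            task = self.store.task(task.id)

        # --- cleanup ---------------------------------------------------
        if task.stage == "staged_out":
            if task.status != Status.STAGING_OUT:
                self.store.set_task_status(task.id, Status.STAGING_OUT)
            shutil.rmtree(scratch, ignore_errors=True)
            self.store.set_task_stage(task.id, "done")
            self.store.set_task_status(task.id, Status.COMPLETE)
            self._log(task, "complete; scratch cleaned")
            self.checkpoint("task.complete")

    def _execute_with_retries(self, task: Task, backend: ComputeBackend, spec: ExecSpec) -> int:
        # the retry budget is per run; a resumed (formerly blocked) task
        # gets a fresh budget, while the stored attempt_count keeps the
        # total across resumes for the audit trail
        local_attempts = 0
        while True:
            local_attempts += 1
            if local_attempts > MAX_ATTEMPTS:
                raise Blocked(
                    f"backend {backend.id!r} lost the task {MAX_ATTEMPTS} times"
                )
            attempts = self.store.bump_attempt(task.id)
            handle = backend.submit(spec)
            self._log(task, f"submitted to {backend.id} as {handle} (attempt {attempts})")
            while True:
                result = backend.poll(handle)
                if result.state == "done":
                    return result.exit_code  # type: ignore[return-value]
                if result.state == "lost":
                    self._log(task, f"attempt {attempts} lost by backend {backend.id}")
                    break
                self.clock.sleep(self.poll_interval)
            self.clock.sleep(self.retry_backoff * (2 ** (attempts - 1)))


def _tail(path: Path, limit: int = 500) -> str:
    try:
        text = path.read_text(errors="replace").strip()
    except OSError:
        return ""
    return text[-limit:]
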