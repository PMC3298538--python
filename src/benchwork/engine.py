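"""Workflow engine: acceptance, dynamic dependency resolution, batch
fan-out, and driving workflows to a terminal state.

Submission is decoupled from processing: ``submit_workflow`` validates the
request, persists it (write-ahead) and returns an id — nothing has executed
when it returns.  Each ``advance`` round then

1. folds finished task statuses into job statuses,
2. fails jobs whose upstream dependency ended in error,
3. resolves jobs whose dependencies are now satisfied — all referenced
   earlier jobs complete and all referenced input files present on their
   storage backend — and expands them into tasks (batch fan-out), and
4. recomputes the workflow status.

A workflow ends ``complete`` iff every job completed, ``error`` once every
job is terminal and at least one failed.  Transient faults surface as the
non-terminal ``blocked`` status; ``resume`` re-offers blocked work after
the user clears the fault.

Batch fan-out: a job with one batchable file parameter matching *n* files
expands into *n* tasks, one per file; with two batchable parameters, files
are paired by minimum total Levenshtein distance (see
:mod:`benchwork.matching`) and one task is created per pair.  A batch that
matches zero files is a job *error* — silent empty fan-out would hide user
mistakes.
"""

from __future__ import annotations

import time
import uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from .compute import ComputeRegistry, TaskRunner
from .credentials import CredentialVault
from .errors import (
    Blocked,
    ConfigurationError,
    CredentialMissing,
    RenderError,
    ValidationError,
)
from .matching import levenshtein, match_files, pair_inputs  # noqa: F401  (module surface)
from .model import (
    FileInput,
    JobOutputRef,
    Literal,
    Status,
    Task,
    TERMINAL,
    Workflow,
    WorkflowRequest,
    classify_arg,
    validate_request,
)
from .persistence import Store
from .registry import Registry, ToolSpec, serialize_registry
from .storage import StorageRouter
from .uris import UriRef


def render_command(tool: ToolSpec, bound_args: dict[str, str]) -> list[str]:
    """Deterministic argument vector for *tool* with *bound_args*.

    Program tokens come first, with ``{param}`` placeholders substituted
    in place; every remaining bound parameter follows in declared order as
    ``switch value`` (no switch token when the switch is empty).  Values
    are single tokens passed verbatim — never through a shell — so spaces
    survive.  An unbound optional parameter is omitted entirely; an unbound
    mandatory one is a rendering error naming the parameter.
    """
    placeholder_names = tool.placeholder_params
    for p in tool.params:
        if p.mandatory and p.name not in bound_args:
            raise RenderError(f"mandatory parameter {p.name!r} is unbound")
    tokens: list[str] = []
    for raw_token in tool.program.split():
        if "{" in raw_token:
            token = raw_token
            for name in placeholder_names:
                marker = "{" + name + "}"
                if marker in token:
                    if name not in bound_args:
                        raise RenderError(
                            f"program placeholder {{{name}}} is unbound"
                        )
                    token = token.replace(marker, bound_args[name])
            tokens.append(token)
        else:
            tokens.append(raw_token)
    for p in tool.params:
        if p.name in placeholder_names or p.name not in bound_args:
            continue
        if p.switch:
            tokens.append(p.switch)
        tokens.append(bound_args[p.name])
    return tokens


class _GenerationError(Exception):
    """Internal: task generation failed; the job goes to error with this text."""


@dataclass
class _ResolvedJob:
    file_lists: dict[str, list[UriRef]]  # param name -> candidate files
    literals: dict[str, str]


class Engine:
    """Glues registry, store, storage, compute and vault together.

    One engine instance is single-user-at-a-time per operation (the desk
    scale analog of the middleware tier); credentials are resolved for the
    submitting user of whichever workflow is being advanced.
    """

    def __init__(
        self,
        registry: Registry,
        store: Store,
        storage: StorageRouter,
        compute: ComputeRegistry,
        vault: CredentialVault | None = None,
        work_root: str | Path = "work",
        task_env: dict[str, str] | None = None,
        checkpoint: Callable[[str], None] | None = None,
        lease_ttl: float = 60.0,
        poll_interval: float = 0.005,
        retry_backoff: float = 0.02,
    ):
        self.registry = registry
        self.store = store
        self.storage = storage
        self.compute = compute
        self.vault = vault
        self.work_root = Path(work_root)
        self.lease_ttl = lease_ttl
        self.checkpoint = checkpoint or (lambda name: None)
        self._active_user: str | None = None
        if storage.credential_resolver is None:
            storage.credential_resolver = self._storage_credential
        self.runner = TaskRunner(
            store=store,
            storage=storage,
            compute=compute,
            registry=registry,
            work_root=self.work_root,
            task_env=task_env,
            credential_getter=self._credential_for,
            checkpoint=self.checkpoint,
            poll_interval=poll_interval,
            retry_backoff=retry_backoff,
        )
        # a restarted engine re-offers any work that was in flight
        store.recover_leases()

    # -- credentials ----------------------------------------------------
    def _credential_for(self, user: str, backend_id: str) -> bytes:
        descriptor = self.registry.backends.get(backend_id)
        if descriptor is None or not descriptor.requires_credential:
            return b""
        if self.vault is None:
            raise CredentialMissing(f"backend {backend_id!r} requires a credential")
        return self.vault.get(user, backend_id)

    def _storage_credential(self, backend_id: str) -> bytes:
        return self._credential_for(self._active_user or "", backend_id)

    # -- submission ------------------------------------------------------
    def submit_workflow(self, request: WorkflowRequest | dict | str) -> str:
        """Validate and persist; returns an id *before* anything executes."""
        if not isinstance(request, WorkflowRequest):
            request = WorkflowRequest.from_json(request)
        diagnostics = validate_request(request, self.registry)
        if diagnostics:
            raise ValidationError("workflow rejected", diagnostics)
        name = request.name or f"workflow-{uuid.uuid4().hex[:8]}"
        jobs = []
        for spec in request.jobs:
            tool = self.registry.tool(spec.tool)
            jobs.append((spec.tool, spec.args, _serialize_tool(tool)))
        wf_id = self.store.create_workflow(
            name=name,
            user=request.user,
            metadata=request.metadata,
            request=request.to_json(),
            jobs=jobs,
        )
        self.checkpoint("submit.persisted")
        return wf_id

    # -- scheduling rounds ----------------------------------------------
    def advance(self, workflow_id: str) -> Workflow:
        """One scheduling round; idempotent when nothing changed."""
        wf = self.store.workflow(workflow_id)
        if wf.status in TERMINAL:
            return wf
        self._active_user = wf.user

        for job in wf.jobs:
            if job.status in TERMINAL or not job.tasks:
                continue
            statuses = {t.status for t in job.tasks}
            if Status.ERROR in statuses:
                new = Status.ERROR
            elif Status.BLOCKED in statuses:
                new = Status.BLOCKED
            elif statuses == {Status.COMPLETE}:
                new = Status.COMPLETE
            else:
                new = Status.RUNNING
            if new != job.status:
                self.store.set_job_status(job.id, new)
                job.status = new

        for job in wf.jobs:
            if job.status in TERMINAL or job.tasks:
                continue
            failed_dep = next(
                (
                    dep
                    for dep in self._dependencies(job)
                    if wf.jobs[dep].status == Status.ERROR
                ),
                None,
            )
            if failed_dep is not None:
                self.store.set_job_status(
                    job.id, Status.ERROR, diagnostic=f"upstream job {failed_dep} failed"
                )
                job.status = Status.ERROR

        for job in wf.jobs:
            if job.status not in (Status.PENDING, Status.BLOCKED) or job.tasks:
                continue
            deps = self._dependencies(job)
            if any(wf.jobs[d].status != Status.COMPLETE for d in deps):
                continue
            try:
                resolved = self._resolve_inputs(job, wf)
            except Blocked as exc:
                self.store.set_job_status(job.id, Status.BLOCKED, diagnostic=exc.reason)
                job.status = Status.BLOCKED
                continue
            except _GenerationError as exc:
                self.store.set_job_status(job.id, Status.ERROR, diagnostic=str(exc))
                job.status = Status.ERROR
                continue
            try:
                drafts, note = self.generate_tasks(job, resolved, wf)
            except _GenerationError as exc:
                self.store.set_job_status(job.id, Status.ERROR, diagnostic=str(exc))
                job.status = Status.ERROR
                continue
            self.store.create_tasks(job.id, wf.id, drafts)
            self.store.set_job_status(job.id, Status.RUNNING, diagnostic=note)
            job.status = Status.RUNNING

        wf = self.store.workflow(workflow_id)
        statuses = [j.status for j in wf.jobs]
        if all(s == Status.COMPLETE for s in statuses):
            new_status = Status.COMPLETE
        elif all(s in TERMINAL for s in statuses):
            new_status = Status.ERROR
        elif any(s == Status.RUNNING for s in statuses):
            new_status = Status.RUNNING
        elif any(s == Status.BLOCKED for s in statuses):
            new_status = Status.BLOCKED
        else:
            new_status = Status.PENDING
        if new_status != wf.status:
            self.store.set_workflow_status(wf.id, new_status)
            wf.status = new_status
        self.checkpoint("advance.end")
        return wf

    def resolve_ready_jobs(self, workflow_id: str) -> list[str]:
        """Ids of jobs whose dependencies are satisfied right now.

        Pure query (no task creation): a job is ready when every referenced
        earlier job is complete and every referenced input file exists on
        its storage backend.  A job whose inputs cannot be checked or are
        missing is moved to *blocked*, not error.
        """
        wf = self.store.workflow(workflow_id)
        self._active_user = wf.user
        ready = []
        def finished(dep_job) -> bool:
            # tolerate an unfolded state: a job whose every task completed
            # counts as finished even before advance folds its status
            return dep_job.status == Status.COMPLETE or (
                bool(dep_job.tasks)
                and all(t.status == Status.COMPLETE for t in dep_job.tasks)
            )

        for job in wf.jobs:
            if job.tasks or job.status not in (Status.PENDING, Status.BLOCKED):
                continue
            deps = self._dependencies(job)
            if not all(finished(wf.jobs[d]) for d in deps):
                continue
            try:
                self._resolve_inputs(job, wf)
            except Blocked as exc:
                self.store.set_job_status(job.id, Status.BLOCKED, diagnostic=exc.reason)
                continue
            except _GenerationError:
                continue
            ready.append(job.id)
        return ready

    def _dependencies(self, job) -> list[int]:
        tool = self.registry.tool(job.tool)
        deps = []
        for p in tool.params:
            raw = job.args.get(p.name)
            if raw is None:
                continue
            value = classify_arg(p, raw)
            if isinstance(value, JobOutputRef):
                deps.append(value.from_job)
        return sorted(set(deps))

    # -- dependency resolution -------------------------------------------
    def _resolve_inputs(self, job, wf: Workflow) -> _ResolvedJob:
        tool = self.registry.tool(job.tool)
        file_lists: dict[str, list[UriRef]] = {}
        literals: dict[str, str] = {}
        for p in tool.params:
            raw = job.args.get(p.name)
            if raw is None:
                continue
            value = classify_arg(p, raw)
            if isinstance(value, Literal):
                literals[p.name] = value.value
            elif isinstance(value, JobOutputRef):
                dep_job = wf.jobs[value.from_job]
                outputs = [
                    UriRef.parse(o["uri"]) for o in self.store.outputs_for_job(dep_job.id)
                ]
                patterns = (
                    [value.pattern]
                    if value.pattern
                    else [a.pattern for a in p.accepts] or ["*"]
                )
                names = [o.basename for o in outputs]
                keep = set()
                for pattern in patterns:
                    keep.update(match_files(names, pattern))
                matched = [o for o in outputs if o.basename in keep]
                if not matched:
                    raise _GenerationError(
                        f"no input satisfies pattern for parameter {p.name!r}"
                        f" (patterns {patterns}, upstream job {value.from_job})"
                    )
                file_lists[p.name] = matched
            elif isinstance(value, FileInput):
                file_lists[p.name] = self._expand_file_arg(p, value.uri)
        return _ResolvedJob(file_lists=file_lists, literals=literals)

    def _expand_file_arg(self, p, uri: UriRef) -> list[UriRef]:
        basename = uri.basename
        if any(ch in basename for ch in "*?["):
            parent = uri.parent
            if not self.storage.exists(parent):
                raise Blocked(f"input directory missing: {parent.render()}")
            names = self.storage.list_dir(parent).files()
            matched = match_files(names, basename)
            if not matched:
                raise _GenerationError(
                    f"no input satisfies pattern for parameter {p.name!r}"
                    f" ({uri.render()})"
                )
            return [parent.join(n) for n in matched]
        if not self.storage.exists(uri):
            raise Blocked(f"input file missing: {uri.render()}")
        if self.storage.is_dir(uri):
            names = self.storage.list_dir(uri).files()
            patterns = [a.pattern for a in p.accepts] or ["*"]
            keep: list[str] = []
            for pattern in patterns:
                for n in match_files(names, pattern):
                    if n not in keep:
                        keep.append(n)
            if not keep:
                raise _GenerationError(
                    f"no input satisfies pattern for parameter {p.name!r}"
                    f" (directory {uri.render()}, patterns {patterns})"
                )
            return [uri.join(n) for n in sorted(keep)]
        return [uri]

    # -- task generation ---------------------------------------------------
    def generate_tasks(
        self, job, resolved: _ResolvedJob, wf: Workflow
    ) -> tuple[list[dict], str | None]:
        """Expand a ready job into task drafts.

        Returns ``(drafts, note)`` where *note* reports non-fatal findings
        (e.g. unpaired leftovers from two-parameter batching).
        """
        tool = self.registry.tool(job.tool)
        batch_params = [
            p.name
            for p in tool.params
            if p.name in resolved.file_lists and p.batchable
        ]
        single_params = [
            p.name
            for p in tool.params
            if p.name in resolved.file_lists and not p.batchable
        ]
        note: str | None = None

        fixed: dict[str, UriRef] = {}
        for name in single_params:
            files = resolved.file_lists[name]
            if len(files) != 1:
                raise _GenerationError(
                    f"parameter {name!r} matched {len(files)} files; expected exactly one"
                )
            fixed[name] = files[0]

        combos: list[dict[str, UriRef]]
        if not batch_params:
            combos = [dict(fixed)]
        elif len(batch_params) == 1:
            name = batch_params[0]
            combos = [{**fixed, name: f} for f in resolved.file_lists[name]]
        elif len(batch_params) == 2:
            name_a, name_b = batch_params
            files_a = resolved.file_lists[name_a]
            files_b = resolved.file_lists[name_b]
            by_name_a = {f.basename: f for f in files_a}
            by_name_b = {f.basename: f for f in files_b}
            pairing = pair_inputs(sorted(by_name_a), sorted(by_name_b))
            combos = [
                {**fixed, name_a: by_name_a[a], name_b: by_name_b[b]}
                for a, b in pairing.pairs
            ]
            leftovers = pairing.leftover_a + pairing.leftover_b
            if leftovers:
                note = f"unpaired inputs left over: {sorted(leftovers)}"
        else:
            raise _GenerationError(
                f"{len(batch_params)} batchable parameters; at most two are supported"
            )
        if not combos:
            raise _GenerationError("no input satisfies pattern (empty batch)")

        drafts = []
        for i, combo in enumerate(combos):
            task_id = f"{job.id}-t{i:04d}"
            scratch_in = self.work_root / wf.id / task_id / "in"
            stage_in: list[tuple[str, str]] = []
            bound = dict(resolved.literals)
            used_names: set[str] = set()
            for pname, src in combo.items():
                staged = src.basename
                if staged in used_names:
                    staged = f"{pname}_{staged}"
                used_names.add(staged)
                stage_in.append((src.render(), staged))
                bound[pname] = str(scratch_in / staged)
            command = render_command(tool, bound)
            dst = self._render_output_location(tool, wf, job, task_id)
            drafts.append(
                {
                    "command": command,
                    "stage_in": stage_in,
                    "stage_out": {
                        "dst": dst.render(),
                        "produces": [pr.pattern for pr in tool.produces],
                    },
                    "inputs": [src.render() for src in combo.values()],
                }
            )
        return drafts, note

    def _render_output_location(self, tool: ToolSpec, wf: Workflow, job, task_id: str) -> UriRef:
        try:
            rendered = tool.output_location.format(
                workflow_id=wf.id,
                workflow_name=wf.name,
                job_index=job.index,
                job_id=job.id,
                tool=tool.name,
                user=wf.user,
                task_id=task_id,
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"tool {tool.name!r}: unknown placeholder {exc} in output_location"
            )
        return UriRef.parse(rendered)

    # -- execution ---------------------------------------------------------
    def poll_ready_tasks(
        self, limit: int | None = None, workflow_id: str | None = None
    ) -> list[Task]:
        """Lease ready tasks (each handed out exactly once per lease TTL)."""
        tasks = self.store.lease_ready(time.time(), self.lease_ttl, limit=limit)
        if workflow_id is not None:
            keep = [t for t in tasks if t.workflow_id == workflow_id]
            for t in tasks:
                if t.workflow_id != workflow_id:
                    self.store.release_lease(t.id)
            tasks = keep
        return tasks

    def run_task(self, task: Task) -> None:
        job = self.store.workflow(task.workflow_id).jobs  # small trees at desk scale
        job = next(j for j in job if j.id == task.job_id)
        wf_user = self.store.workflow(task.workflow_id).user
        self._active_user = wf_user
        tool = self.registry.tool(job.tool)
        self.runner.run_task(task, wf_user, tool.exec_backend)

    def report_status(self, task_id: str, new_status: Status, reason: str | None = None) -> None:
        self.store.set_task_status(task_id, new_status, blocked_reason=reason)

    def report_syslog(self, task_id: str, message: str) -> None:
        self.store.append_syslog(task_id, message)

    # -- driving -----------------------------------------------------------
    def drive(self, workflow_id: str, max_rounds: int = 10_000) -> Status:
        """Run scheduling rounds until the workflow is terminal or stuck
        on a transient fault (blocked)."""
        idle_rounds = 0
        for _ in range(max_rounds):
            wf = self.advance(workflow_id)
            if wf.status in TERMINAL:
                return wf.status
            tasks = self.poll_ready_tasks(workflow_id=workflow_id)
            if not tasks:
                idle_rounds += 1
                if wf.status == Status.BLOCKED or idle_rounds >= 3:
                    return wf.status
                continue
            idle_rounds = 0
            for task in tasks:
                self.run_task(task)
            self.checkpoint("drive.round")
        return self.store.workflow(workflow_id).status

    def resume(self, workflow_id: str) -> Status:
        """Re-offer blocked work (after the user has cleared the fault)."""
        wf = self.store.workflow(workflow_id)
        for job in wf.jobs:
            for task in job.tasks:
                if task.status == Status.BLOCKED:
                    self.store.set_task_status(task.id, Status.READY)
            if job.status == Status.BLOCKED:
                self.store.set_job_status(
                    job.id,
                    Status.RUNNING if job.tasks else Status.PENDING,
                    diagnostic=None,
                )
        if wf.status == Status.BLOCKED:
            self.store.set_workflow_status(wf.id, Status.PENDING)
        return self.drive(workflow_id)

    def drive_all(self) -> dict[str, Status]:
        out = {}
        for wf_id in self.store.workflow_ids():
            wf = self.store.workflow(wf_id)
            if wf.status not in TERMINAL:
                out[wf_id] = self.drive(wf_id)
        return out


def _serialize_tool(tool: ToolSpec) -> dict:
    reg = Registry(tools={tool.name: tool})
    return serialize_registry(reg)["tools"][0]
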