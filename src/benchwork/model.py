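"""Execution hierarchy: workflow request -> jobs -> tasks, and the status
state machine shared by all three levels.

A *workflow* is the user-submitted ordered list of jobs.  A *job* is one
tool invocation whose file dependencies may point at the output of an
earlier job ("``{"from_job": k}``" references, 0-based, strictly earlier).
Once a job's dependencies resolve it expands into one or more *tasks*, each
a single concrete command execution with its own stage-in/stage-out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

from .errors import ContractViolation, ValidationError
from .registry import ParamSpec, Registry, ToolSpec
from .uris import UriRef


class Status(str, Enum):
    PENDING = "pending"
    READY = "ready"
    STAGING_IN = "staging_in"
    RUNNING = "running"
    STAGING_OUT = "staging_out"
    BLOCKED = "blocked"
    ERROR = "error"
    COMPLETE = "complete"


TERMINAL = frozenset({Status.ERROR, Status.COMPLETE})

_NEXT = {
    Status.PENDING: {Status.READY},
    Status.READY: {Status.STAGING_IN},
    Status.STAGING_IN: {Status.RUNNING},
    Status.RUNNING: {Status.STAGING_OUT},
    Status.STAGING_OUT: {Status.COMPLETE},
}


def check_transition(old: Status, new: Status, prior: Status | None = None) -> None:
    """Enforce the task status state machine; illegal moves are bugs, not
    user errors, hence :class:`ContractViolation`."""
    if old == new:
        return
    if old in TERMINAL:
        raise ContractViolation(f"illegal transition {old.value} -> {new.value} (terminal)")
    if new in (Status.BLOCKED, Status.ERROR):
        return
    if old == Status.BLOCKED:
        # resume: back to the recorded prior state, or re-offered as ready
        if new == Status.READY or (prior is not None and new == prior):
            return
        raise ContractViolation(f"illegal resume {old.value} -> {new.value}")
    if new in _NEXT.get(old, ()):
        return
    raise ContractViolation(f"illegal transition {old.value} -> {new.value}")


# ---------------------------------------------------------------------------
# argument values

@dataclass(frozen=True)
class Literal:
    value: str


@dataclass(frozen=True)
class FileInput:
    uri: UriRef  # basename may contain glob metacharacters


@dataclass(frozen=True)
class JobOutputRef:
    from_job: int
    pattern: str | None = None


ArgValue = Literal | FileInput | JobOutputRef


def classify_arg(param: ParamSpec, raw: Any) -> ArgValue:
    """Interpret a raw JSON argument value in light of the parameter spec."""
    if isinstance(raw, dict):
        if "from_job" in raw:
            extra = set(raw) - {"from_job", "pattern"}
            if extra:
                raise ValidationError(f"param {param.name!r}: unknown keys {sorted(extra)}")
            if not param.takes_files:
                raise ValidationError(
                    f"param {param.name!r} does not accept previous-job output"
                )
            k = raw["from_job"]
            if not isinstance(k, int) or isinstance(k, bool):
                raise ValidationError(f"param {param.name!r}: from_job must be an integer")
            return JobOutputRef(from_job=k, pattern=raw.get("pattern"))
        if "uri" in raw:
            return FileInput(uri=UriRef.parse(raw["uri"]))
        if "literal" in raw:
            return Literal(value=str(raw["literal"]))
        raise ValidationError(f"param {param.name!r}: unrecognized argument object {raw!r}")
    if isinstance(raw, (str, int, float)):
        text = str(raw)
        if param.takes_files:
            return FileInput(uri=UriRef.parse(text))
        return Literal(value=text)
    raise ValidationError(f"param {param.name!r}: unsupported argument type {type(raw).__name__}")


# ---------------------------------------------------------------------------
# requests

@dataclass
class JobSpec:
    tool: str
    args: dict[str, Any] = field(default_factory=dict)  # raw JSON values

    def to_json(self) -> dict:
        return {"tool": self.tool, "args": self.args}


@dataclass
class WorkflowRequest:
    user: str
    jobs: list[JobSpec]
    name: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def from_json(doc: dict | str) -> "WorkflowRequest":
        if isinstance(doc, str):
            doc = json.loads(doc)
        unknown = set(doc) - {"name", "user", "metadata", "jobs"}
        if unknown:
            raise ValidationError(f"workflow: unknown keys {sorted(unknown)}")
        jobs = []
        for i, j in enumerate(doc.get("jobs", [])):
            extra = set(j) - {"tool", "args"}
            if extra:
                raise ValidationError(f"job {i}: unknown keys {sorted(extra)}")
            if "tool" not in j:
                raise ValidationError(f"job {i}: missing tool")
            jobs.append(JobSpec(tool=j["tool"], args=dict(j.get("args", {}))))
        return WorkflowRequest(
            user=doc.get("user", ""),
            jobs=jobs,
            name=doc.get("name"),
            metadata=dict(doc.get("metadata", {})),
        )

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "user": self.user,
            "metadata": self.metadata,
            "jobs": [j.to_json() for j in self.jobs],
        }


def validate_request(request: WorkflowRequest, registry: Registry) -> list[str]:
    """Per-job diagnostics; an empty list means the request is acceptable."""
    diags: list[str] = []
    if not request.jobs:
        diags.append("workflow has no jobs")
        return diags
    if not request.user:
        diags.append("workflow has no user")
        return diags
    try:
        grant = registry.user(request.user)
    except Exception:
        diags.append(f"unknown user {request.user!r}")
        return diags
    granted = set(grant.tool_names)
    for i, job in enumerate(request.jobs):
        where = f"job {i}"
        if job.tool not in registry.tools:
            diags.append(f"{where}: unknown tool {job.tool!r}")
            continue
        if job.tool not in granted:
            diags.append(f"{where}: tool {job.tool!r} not granted to user {request.user!r}")
            continue
        tool = registry.tool(job.tool)
        declared = {p.name for p in tool.params}
        for name in job.args:
            if name not in declared:
                diags.append(f"{where}: unknown parameter {name!r} for tool {job.tool!r}")
        for p in tool.params:
            raw = job.args.get(p.name)
            if raw is None:
                if p.mandatory:
                    diags.append(f"{where}: mandatory parameter {p.name!r} not supplied")
                continue
            try:
                value = classify_arg(p, raw)
            except ValidationError as exc:
                diags.append(f"{where}: {exc}")
                continue
            if isinstance(value, JobOutputRef):
                if not (0 <= value.from_job < i):
                    diags.append(
                        f"{where}: from_job {value.from_job} must reference a strictly"
                        f" earlier job (0..{i - 1})"
                    )
    return diags


# ---------------------------------------------------------------------------
# runtime records (as materialized by the persistence store)

#: lifecycle stage markers persisted as a task progresses; resume restarts
#: the first stage not yet marked done, never an earlier completed one
STAGES = ("new", "staged_in", "executed", "staged_out", "done")


@dataclass
class Task:
    id: str
    job_id: str
    workflow_id: str
    command: list[str]
    stage_in: list[tuple[str, str]]  # (src URI, staged basename)
    stage_out: dict  # {"out_dir": scratch-out URI, "dst": destination URI}
    status: Status = Status.PENDING
    prior_status: Status | None = None
    stage: str = "new"
    exit_code: int | None = None
    attempt_count: int = 0
    lease_until: float | None = None
    scratch: str | None = None
    blocked_reason: str | None = None


@dataclass
class Job:
    id: str
    workflow_id: str
    index: int
    tool: str
    args: dict[str, Any]
    status: Status = Status.PENDING
    diagnostic: str | None = None
    tool_spec: dict | None = None
    tasks: list[Task] = field(default_factory=list)

    @property
    def unresolved(self) -> bool:
        return not self.tasks


@dataclass
class Workflow:
    id: str
    name: str
    user: str
    metadata: dict[str, str]
    status: Status
    created_utc: str
    seq: int
    request: dict
    jobs: list[Job] = field(default_factory=list)
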