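"""Declarative administration layer.

Tools, backends, users and access grants are described in one config
document (JSON canonical, YAML accepted) with three sections::

    {"schema_version": 1,
     "backends": [{"id": "localexec", "kind": "compute", "scheme": "localexec"}, ...],
     "tools":    [{"name": "wordcount", "program": "wc", ...}, ...],
     "users":    [{"name": "alice", "tools": ["wordcount"], "backends": ["localexec"]}]}

Adding a tool is a pure config edit — no code changes anywhere else in the
system.  The schema is strict: unknown keys are rejected, because a silent
typo in a tool record is the main administrative hazard.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError, NotFoundError, ValidationError
from .matching import validate_glob
from .errors import PatternError

SCHEMA_VERSION = 1

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")

SOURCE_KINDS = ("user-literal", "input-file", "previous-job-output")


@dataclass(frozen=True)
class FileTypePattern:
    """A unix-style filename glob describing a file type (e.g. ``*.fa``)."""

    pattern: str

    def __post_init__(self):
        try:
            validate_glob(self.pattern)
        except PatternError as exc:
            raise ValidationError(str(exc)) from exc


@dataclass(frozen=True)
class ParamSpec:
    """One declared tool parameter.

    ``switch`` is the token emitted before the value (may be empty for
    positional values).  ``accepts`` lists the file types the parameter
    takes; empty means a free-form literal value.  A ``batchable`` parameter
    fans out into one task per matching file.
    """

    name: str
    switch: str = ""
    mandatory: bool = False
    accepts: tuple[FileTypePattern, ...] = ()
    batchable: bool = False
    source_kind: str = "user-literal"

    def __post_init__(self):
        if self.source_kind not in SOURCE_KINDS:
            raise ValidationError(
                f"param {self.name!r}: unknown source_kind {self.source_kind!r}"
            )
        if self.batchable and not self.accepts:
            raise ValidationError(
                f"param {self.name!r}: batchable requires non-empty accepts"
            )
        if self.source_kind == "previous-job-output" and not self.accepts:
            raise ValidationError(
                f"param {self.name!r}: previous-job-output requires non-empty accepts"
            )

    @property
    def takes_files(self) -> bool:
        return bool(self.accepts)


@dataclass(frozen=True)
class ToolSpec:
    """Declarative description of a runnable program.

    ``program`` is a whitespace-split command template; a token may embed
    ``{param_name}`` placeholders, each of which must name exactly one
    declared parameter.  Parameters not consumed by a placeholder are
    appended in declared order as ``switch value`` token pairs.
    ``output_location`` is a URI template (``{workflow_id}``, ``{job_index}``,
    ``{job_id}``, ``{tool}``, ``{user}`` substitutions) telling the engine
    where stage-out puts result files.
    """

    name: str
    program: str
    exec_backend: str
    output_location: str
    params: tuple[ParamSpec, ...] = ()
    produces: tuple[FileTypePattern, ...] = ()

    def __post_init__(self):
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValidationError(f"tool {self.name!r}: duplicate parameter names")
        declared = set(names)
        for ph in _PLACEHOLDER_RE.findall(self.program):
            if ph not in declared:
                raise ValidationError(
                    f"tool {self.name!r}: program placeholder {{{ph}}} "
                    f"matches no declared parameter"
                )

    def param(self, name: str) -> ParamSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise NotFoundError(f"tool {self.name!r} has no parameter {name!r}")

    @property
    def placeholder_params(self) -> set[str]:
        return set(_PLACEHOLDER_RE.findall(self.program))


@dataclass(frozen=True)
class BackendDescriptor:
    """A storage or compute endpoint, selected by id, dispatched by scheme."""

    id: str
    kind: str  # "storage" | "compute"
    scheme: str
    endpoint: str = ""
    requires_credential: bool = False
    reachable: bool = True  # mock backends may be configured unreachable

    def __post_init__(self):
        if self.kind not in ("storage", "compute"):
            raise ValidationError(f"backend {self.id!r}: kind must be storage|compute")


@dataclass(frozen=True)
class UserGrant:
    user: str
    tool_names: tuple[str, ...] = ()
    backend_ids: tuple[str, ...] = ()


@dataclass
class Registry:
    """Validated view of one config document."""

    tools: dict[str, ToolSpec] = field(default_factory=dict)
    backends: dict[str, BackendDescriptor] = field(default_factory=dict)
    users: dict[str, UserGrant] = field(default_factory=dict)

    def tool(self, name: str) -> ToolSpec:
        try:
            return self.tools[name]
        except KeyError:
            raise NotFoundError(f"unknown tool {name!r}") from None

    def backend(self, backend_id: str) -> BackendDescriptor:
        try:
            return self.backends[backend_id]
        except KeyError:
            raise NotFoundError(f"unknown backend {backend_id!r}") from None

    def backend_for_scheme(self, scheme: str, kind: str = "storage") -> BackendDescriptor | None:
        for b in self.backends.values():
            if b.scheme == scheme and b.kind == kind:
                return b
        return None

    def user(self, name: str) -> UserGrant:
        try:
            return self.users[name]
        except KeyError:
            raise NotFoundError(f"unknown user {name!r}") from None


# ---------------------------------------------------------------------------
# loading / serialization

_TOOL_KEYS = {"name", "program", "exec_backend", "output_location", "params", "produces"}
_PARAM_KEYS = {"name", "switch", "mandatory", "accepts", "batchable", "source_kind"}
_BACKEND_KEYS = {"id", "kind", "scheme", "endpoint", "requires_credential", "reachable"}
_USER_KEYS = {"name", "tools", "backends"}
_TOP_KEYS = {"schema_version", "tools", "backends", "users"}


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(
            f"{where}: unknown config key(s) {sorted(unknown)}"
        )


def load_registry(source: str | Path | io.TextIOBase | dict) -> Registry:
    """Load and validate a registry config.

    *source* may be a path, an open text stream, a raw document string, or
    an already-parsed dict.  JSON is canonical; YAML is accepted.
    """
    doc = _read_document(source)
    if not isinstance(doc, dict):
        raise ValidationError("registry config must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "registry")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"unrecognized schema_version {version!r} (expected {SCHEMA_VERSION})"
        )

    reg = Registry()
    for raw in doc.get("backends", []):
        _reject_unknown(raw, _BACKEND_KEYS, f"backend {raw.get('id')!r}")
        be = BackendDescriptor(**raw)
        if be.id in reg.backends:
            raise ValidationError(f"duplicate backend id {be.id!r}")
        reg.backends[be.id] = be

    for raw in doc.get("tools", []):
        tool = _parse_tool(raw)
        if tool.name in reg.tools:
            raise ValidationError(f"duplicate tool name {tool.name!r}")
        be = reg.backends.get(tool.exec_backend)
        if be is None:
            raise ConfigurationError(
                f"tool {tool.name!r}: exec_backend {tool.exec_backend!r} is not registered"
            )
        if be.kind != "compute":
            raise ConfigurationError(
                f"tool {tool.name!r}: backend {be.id!r} is not a compute backend"
            )
        reg.tools[tool.name] = tool

    for raw in doc.get("users", []):
        _reject_unknown(raw, _USER_KEYS, f"user {raw.get('name')!r}")
        grant = UserGrant(
            user=raw["name"],
            tool_names=tuple(raw.get("tools", [])),
            backend_ids=tuple(raw.get("backends", [])),
        )
        if grant.user in reg.users:
            raise ValidationError(f"duplicate user {grant.user!r}")
        for t in grant.tool_names:
            if t not in reg.tools:
                raise ConfigurationError(
                    f"user {grant.user!r}: granted tool {t!r} does not exist"
                )
        for b in grant.backend_ids:
            if b not in reg.backends:
                raise ConfigurationError(
                    f"user {grant.user!r}: granted backend {b!r} does not exist"
                )
        reg.users[grant.user] = grant

    return reg


def _parse_tool(raw: dict) -> ToolSpec:
    name = raw.get("name", "<unnamed>")
    _reject_unknown(raw, _TOOL_KEYS, f"tool {name!r}")
    for key in ("name", "program", "exec_backend", "output_location"):
        if key not in raw:
            raise ValidationError(f"tool {name!r}: missing required key {key!r}")
    params = []
    for p in raw.get("params", []):
        _reject_unknown(p, _PARAM_KEYS, f"tool {name!r} param {p.get('name')!r}")
        if "name" not in p:
            raise ValidationError(f"tool {name!r}: parameter without a name")
        params.append(
            ParamSpec(
                name=p["name"],
                switch=p.get("switch", ""),
                mandatory=bool(p.get("mandatory", False)),
                accepts=tuple(FileTypePattern(x) for x in p.get("accepts", [])),
                batchable=bool(p.get("batchable", False)),
                source_kind=p.get("source_kind", "user-literal"),
            )
        )
    return ToolSpec(
        name=raw["name"],
        program=raw["program"],
        exec_backend=raw["exec_backend"],
        output_location=raw["output_location"],
        params=tuple(params),
        produces=tuple(FileTypePattern(x) for x in raw.get("produces", [])),
    )


def serialize_registry(reg: Registry) -> dict:
    """Inverse of :func:`load_registry`; ``load_registry(serialize_registry(r))`` == r."""
    return {
        "schema_version": SCHEMA_VERSION,
        "backends": [
            {
                "id": b.id,
                "kind": b.kind,
                "scheme": b.scheme,
                "endpoint": b.endpoint,
                "requires_credential": b.requires_credential,
                "reachable": b.reachable,
            }
            for b in reg.backends.values()
        ],
        "tools": [
            {
                "name": t.name,
                "program": t.program,
                "exec_backend": t.exec_backend,
                "output_location": t.output_location,
                "params": [
                    {
                        "name": p.name,
                        "switch": p.switch,
                        "mandatory": p.mandatory,
                        "accepts": [a.pattern for a in p.accepts],
                        "batchable": p.batchable,
                        "source_kind": p.source_kind,
                    }
                    for p in t.params
                ],
                "produces": [pr.pattern for pr in t.produces],
            }
            for t in reg.tools.values()
        ],
        "users": [
            {
                "name": u.user,
                "tools": list(u.tool_names),
                "backends": list(u.backend_ids),
            }
            for u in reg.users.values()
        ],
    }


def _read_document(source) -> Any:
    if isinstance(source, dict):
        return source
    if isinstance(source, (io.TextIOBase, io.StringIO)) or hasattr(source, "read"):
        text = source.read()
        return _parse_text(text, name=getattr(source, "name", "<stream>"))
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        path = Path(source)
        return _parse_text(path.read_text(), name=str(path))
    if isinstance(source, str):
        return _parse_text(source, name="<string>")
    raise ValidationError(f"cannot read registry config from {type(source).__name__}")


def _parse_text(text: str, name: str) -> Any:
    if name.endswith((".yml", ".yaml")):
        return yaml.safe_load(text)
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        try:
            return yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValidationError(f"config {name} parses as neither JSON nor YAML: {exc}")


# ---------------------------------------------------------------------------
# queries

def tools_for_user(registry: Registry, user: str) -> list[ToolSpec]:
    """The tools granted to *user*, in registry declaration order."""
    grant = registry.user(user)
    return [t for t in registry.tools.values() if t.name in set(grant.tool_names)]


@dataclass
class ToolReport:
    """Preflight findings for one tool (empty findings == ready to run)."""

    tool: str
    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


def validate_tool_against_backends(
    registry: Registry,
    tool_name: str,
    credential_check=None,
) -> ToolReport:
    """Admin preflight: report missing credentials and unreachable backends.

    *credential_check* is an optional callable ``(backend_id) -> bool``
    saying whether a credential is on file for that backend (typically bound
    to a vault and a user).
    """
    tool = registry.tool(tool_name)
    report = ToolReport(tool=tool_name)
    backend_ids = [tool.exec_backend]
    out_scheme = None
    try:
        from .uris import UriRef

        out_scheme = UriRef.parse(
            tool.output_location.format(
                workflow_id="wf", job_index=0, job_id="j", tool=tool.name, user="u"
            )
        ).scheme
    except Exception:
        report.findings.append(
            f"output_location {tool.output_location!r} is not a valid URI template"
        )
    if out_scheme is not None:
        storage_be = registry.backend_for_scheme(out_scheme, kind="storage")
        if storage_be is not None:
            backend_ids.append(storage_be.id)
    for bid in backend_ids:
        be = registry.backend(bid)
        if not be.reachable:
            report.findings.append(f"backend unreachable: {bid}")
        if be.requires_credential and credential_check is not None:
            if not credential_check(bid):
                report.findings.append(f"credential missing: {bid}")
        elif be.requires_credential and credential_check is None:
            report.findings.append(f"credential missing: {bid}")
    return report


def export_tools_json(registry: Registry, user: str) -> list[dict]:
    """Tool list with parameter metadata for the CLI (JSON-ready)."""
    out = []
    for t in tools_for_user(registry, user):
        out.append(
            {
                "name": t.name,
                "backend": t.exec_backend,
                "params": [
                    {
                        "name": p.name,
                        "switch": p.switch,
                        "mandatory": p.mandatory,
                        "accepts": [a.pattern for a in p.accepts],
                        "batchable": p.batchable,
                        "source_kind": p.source_kind,
                    }
                    for p in t.params
                ],
                "produces": [pr.pattern for pr in t.produces],
            }
        )
    return out
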