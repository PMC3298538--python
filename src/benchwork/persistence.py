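"""Durable store: workflows/jobs/tasks, syslog, provenance, snapshots.

A single-file embedded SQLite database is the write-ahead system of record:
every mutation is committed before the call returns, so a workflow
acknowledged by ``submit_workflow`` survives an immediate crash, and a
restarted engine picks up exactly where the database says things stood.
Result files never live in the store — only their URIs and checksums do.

A *snapshot* is an explicit, versioned JSON export of the full state
(including in-flight task continuations: stage markers, attempt counts,
lease bookkeeping) that can be loaded into a fresh store.  Snapshots never
contain plaintext secrets; credential records are stored ciphertext-only.

Ordering of audit records uses a global monotonic sequence number next to
the UTC timestamp, so provenance ordering does not depend on clock
resolution or skew.
"""

from __future__ import annotations

import json
import sqlite3
import uuid
from datetime import datetime, timezone
from pathlib import Path

from .errors import NotFoundError, SchemaMismatch
from .model import Job, Status, Task, Workflow, check_transition

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS workflows (
    id TEXT PRIMARY KEY, name TEXT, user TEXT, metadata TEXT,
    status TEXT, created_utc TEXT, seq INTEGER, request TEXT);
CREATE TABLE IF NOT EXISTS jobs (
    id TEXT PRIMARY KEY, workflow_id TEXT, idx INTEGER, tool TEXT,
    args TEXT, status TEXT, diagnostic TEXT, tool_spec TEXT);
CREATE TABLE IF NOT EXISTS tasks (
    id TEXT PRIMARY KEY, job_id TEXT, workflow_id TEXT,
    command TEXT, stage_in TEXT, stage_out TEXT,
    status TEXT, prior_status TEXT, stage TEXT,
    exit_code INTEGER, attempt_count INTEGER, lease_until REAL,
    scratch TEXT, blocked_reason TEXT);
CREATE TABLE IF NOT EXISTS syslog (
    rowid INTEGER PRIMARY KEY AUTOINCREMENT,
    task_id TEXT, seq INTEGER, ts_utc TEXT, message TEXT);
CREATE TABLE IF NOT EXISTS transfers (
    rowid INTEGER PRIMARY KEY AUTOINCREMENT,
    task_id TEXT, dst_uri TEXT, sha256 TEXT, nbytes INTEGER,
    seq INTEGER, ts_utc TEXT);
CREATE TABLE IF NOT EXISTS task_inputs (
    rowid INTEGER PRIMARY KEY AUTOINCREMENT, task_id TEXT, uri TEXT);
CREATE TABLE IF NOT EXISTS credentials (
    user TEXT, backend_id TEXT, payload TEXT, expires_at REAL,
    PRIMARY KEY (user, backend_id));
"""

_TABLES = (
    "workflows",
    "jobs",
    "tasks",
    "syslog",
    "transfers",
    "task_inputs",
    "credentials",
)


def _now_utc() -> str:
    return datetime.now(timezone.utc).isoformat()


class Store:
    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._db = sqlite3.connect(self.path)
        self._db.row_factory = sqlite3.Row
        self._db.executescript(_SCHEMA)
        cur = self._db.execute("SELECT value FROM meta WHERE key='schema_version'")
        row = cur.fetchone()
        if row is None:
            self._db.execute(
                "INSERT INTO meta (key, value) VALUES ('schema_version', ?)",
                (str(SCHEMA_VERSION),),
            )
            self._db.execute("INSERT INTO meta (key, value) VALUES ('seq', '0')")
            self._db.commit()
        elif int(row["value"]) != SCHEMA_VERSION:
            raise SchemaMismatch(
                f"store at {self.path} has schema version {row['value']},"
                f" this build understands {SCHEMA_VERSION}"
            )

    def close(self) -> None:
        self._db.close()

    # -- sequencing ---------------------------------------------------
    def next_seq(self) -> int:
        cur = self._db.execute(
            "UPDATE meta SET value = CAST(value AS INTEGER) + 1 WHERE key='seq' "
            "RETURNING value"
        )
        value = int(cur.fetchone()[0])
        self._db.commit()
        return value

    # -- workflow lifecycle -------------------------------------------
    def create_workflow(
        self,
        name: str,
        user: str,
        metadata: dict,
        request: dict,
        jobs: list[tuple[str, dict, dict | None]],  # (tool, args, tool_spec)
    ) -> str:
        """Persist a workflow and its job rows in one transaction.

        Nothing is visible unless everything is (no partial persistence),
        and the commit happens before the id is returned — the write-ahead
        guarantee submission relies on.
        """
        wf_id = "wf-" + uuid.uuid4().hex[:12]
        seq = self.next_seq()
        with self._db:
            self._db.execute(
                "INSERT INTO workflows (id,name,user,metadata,status,created_utc,seq,request)"
                " VALUES (?,?,?,?,?,?,?,?)",
                (
                    wf_id,
                    name,
                    user,
                    json.dumps(metadata),
                    Status.PENDING.value,
                    _now_utc(),
                    seq,
                    json.dumps(request),
                ),
            )
            for idx, (tool, args, tool_spec) in enumerate(jobs):
                self._db.execute(
                    "INSERT INTO jobs (id,workflow_id,idx,tool,args,status,diagnostic,tool_spec)"
                    " VALUES (?,?,?,?,?,?,?,?)",
                    (
                        f"{wf_id}-j{idx}",
                        wf_id,
                        idx,
                        tool,
                        json.dumps(args),
                        Status.PENDING.value,
                        None,
                        json.dumps(tool_spec) if tool_spec else None,
                    ),
                )
        return wf_id

    def workflow(self, wf_id: str) -> Workflow:
        row = self._db.execute("SELECT * FROM workflows WHERE id=?", (wf_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown workflow {wf_id!r}")
        wf = Workflow(
            id=row["id"],
            name=row["name"],
            user=row["user"],
            metadata=json.loads(row["metadata"]),
            status=Status(row["status"]),
            created_utc=row["created_utc"],
            seq=row["seq"],
            request=json.loads(row["request"]),
        )
        for jrow in self._db.execute(
            "SELECT * FROM jobs WHERE workflow_id=? ORDER BY idx", (wf_id,)
        ):
            job = Job(
                id=jrow["id"],
                workflow_id=wf_id,
                index=jrow["idx"],
                tool=jrow["tool"],
                args=json.loads(jrow["args"]),
                status=Status(jrow["status"]),
                diagnostic=jrow["diagnostic"],
                tool_spec=json.loads(jrow["tool_spec"]) if jrow["tool_spec"] else None,
            )
            for trow in self._db.execute(
                "SELECT * FROM tasks WHERE job_id=? ORDER BY id", (job.id,)
            ):
                job.tasks.append(self._task_from_row(trow))
            wf.jobs.append(job)
        return wf

    def workflow_ids(self) -> list[str]:
        return [
            r["id"]
            for r in self._db.execute("SELECT id FROM workflows ORDER BY seq")
        ]

    @staticmethod
    def _task_from_row(row) -> Task:
        return Task(
            id=row["id"],
            job_id=row["job_id"],
            workflow_id=row["workflow_id"],
            command=json.loads(row["command"]),
            stage_in=[tuple(x) for x in json.loads(row["stage_in"])],
            stage_out=json.loads(row["stage_out"]),
            status=Status(row["status"]),
            prior_status=Status(row["prior_status"]) if row["prior_status"] else None,
            stage=row["stage"],
            exit_code=row["exit_code"],
            attempt_count=row["attempt_count"],
            lease_until=row["lease_until"],
            scratch=row["scratch"],
            blocked_reason=row["blocked_reason"],
        )

    def task(self, task_id: str) -> Task:
        row = self._db.execute("SELECT * FROM tasks WHERE id=?", (task_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown task {task_id!r}")
        return self._task_from_row(row)

    def create_tasks(self, job_id: str, workflow_id: str, drafts: list[dict]) -> list[str]:
        """Insert the tasks of one job atomically; returns the new ids."""
        ids = []
        with self._db:
            for i, d in enumerate(drafts):
                task_id = f"{job_id}-t{i:04d}"
                ids.append(task_id)
                self._db.execute(
                    "INSERT INTO tasks (id,job_id,workflow_id,command,stage_in,stage_out,"
                    "status,prior_status,stage,exit_code,attempt_count,lease_until,"
                    "scratch,blocked_reason) VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                    (
                        task_id,
                        job_id,
                        workflow_id,
                        json.dumps(d["command"]),
                        json.dumps(d["stage_in"]),
                        json.dumps(d["stage_out"]),
                        Status.READY.value,
                        None,
                        "new",
                        None,
                        0,
                        None,
                        None,
                        None,
                    ),
                )
                for uri in d.get("inputs", []):
                    self._db.execute(
                        "INSERT INTO task_inputs (task_id, uri) VALUES (?,?)",
                        (task_id, uri),
                    )
        return ids

    # -- status updates -----------------------------------------------
    def set_workflow_status(self, wf_id: str, status: Status) -> None:
        with self._db:
            self._db.execute(
                "UPDATE workflows SET status=? WHERE id=?", (status.value, wf_id)
            )

    def set_job_status(self, job_id: str, status: Status, diagnostic: str | None = None) -> None:
        with self._db:
            if diagnostic is None:
                self._db.execute(
                    "UPDATE jobs SET status=? WHERE id=?", (status.value, job_id)
                )
            else:
                self._db.execute(
                    "UPDATE jobs SET status=?, diagnostic=? WHERE id=?",
                    (status.value, diagnostic, job_id),
                )

    def set_task_status(
        self, task_id: str, new: Status, blocked_reason: str | None = None
    ) -> None:
        """Persist a task status change, enforcing the legal-transition map.

        The update is committed before this returns (status persisted before
        acknowledgement).  Moving to ``blocked`` records the prior state;
        leaving ``blocked`` clears it.
        """
        row = self._db.execute(
            "SELECT status, prior_status FROM tasks WHERE id=?", (task_id,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"unknown task {task_id!r}")
        old = Status(row["status"])
        prior = Status(row["prior_status"]) if row["prior_status"] else None
        check_transition(old, new, prior)
        with self._db:
            if new == Status.BLOCKED:
                self._db.execute(
                    "UPDATE tasks SET status=?, prior_status=?, blocked_reason=?,"
                    " lease_until=NULL WHERE id=?",
                    (new.value, old.value, blocked_reason, task_id),
                )
            else:
                self._db.execute(
                    "UPDATE tasks SET status=?, prior_status=NULL, blocked_reason=NULL"
                    " WHERE id=?",
                    (new.value, task_id),
                )

    def set_task_stage(self, task_id: str, stage: str, exit_code: int | None = None) -> None:
        with self._db:
            if exit_code is None:
                self._db.execute(
                    "UPDATE tasks SET stage=? WHERE id=?", (stage, task_id)
                )
            else:
                self._db.execute(
                    "UPDATE tasks SET stage=?, exit_code=? WHERE id=?",
                    (stage, exit_code, task_id),
                )

    def set_task_scratch(self, task_id: str, scratch: str) -> None:
        with self._db:
            self._db.execute("UPDATE tasks SET scratch=? WHERE id=?", (scratch, task_id))

    def bump_attempt(self, task_id: str) -> int:
        with self._db:
            cur = self._db.execute(
                "UPDATE tasks SET attempt_count = attempt_count + 1 WHERE id=?"
                " RETURNING attempt_count",
                (task_id,),
            )
            return int(cur.fetchone()[0])

    # -- ready-task queue (pull-based, exactly-once leases) -------------
    def lease_ready(self, now: float, ttl: float, limit: int | None = None) -> list[Task]:
        """Atomically lease ready tasks: each is handed out once until its
        lease expires without progress, then re-offered."""
        self._db.execute("BEGIN IMMEDIATE")
        try:
            query = (
                "SELECT id FROM tasks WHERE status=? AND"
                " (lease_until IS NULL OR lease_until < ?) ORDER BY id"
            )
            params: list = [Status.READY.value, now]
            if limit is not None:
                query += " LIMIT ?"
                params.append(limit)
            ids = [r["id"] for r in self._db.execute(query, params)]
            for task_id in ids:
                self._db.execute(
                    "UPDATE tasks SET lease_until=? WHERE id=?", (now + ttl, task_id)
                )
            self._db.commit()
        except Exception:
            self._db.rollback()
            raise
        return [self.task(i) for i in ids]

    def release_lease(self, task_id: str) -> None:
        with self._db:
            self._db.execute("UPDATE tasks SET lease_until=NULL WHERE id=?", (task_id,))

    def recover_leases(self) -> int:
        """Startup recovery: re-offer every in-flight task.

        Tasks caught mid-lifecycle (staging/running at the time of the
        crash) return to ``ready`` with their stage markers intact, so
        resume restarts the last incomplete stage only.
        """
        transient = (
            Status.STAGING_IN.value,
            Status.RUNNING.value,
            Status.STAGING_OUT.value,
        )
        with self._db:
            cur = self._db.execute(
                f"UPDATE tasks SET status=?, lease_until=NULL WHERE status IN ({','.join('?' * len(transient))})",
                (Status.READY.value, *transient),
            )
            self._db.execute("UPDATE tasks SET lease_until=NULL WHERE lease_until IS NOT NULL")
            return cur.rowcount

    # -- syslog ---------------------------------------------------------
    def append_syslog(self, task_id: str, message: str) -> None:
        seq = self.next_seq()
        with self._db:
            self._db.execute(
                "INSERT INTO syslog (task_id, seq, ts_utc, message) VALUES (?,?,?,?)",
                (task_id, seq, _now_utc(), message),
            )

    def syslog(self, task_id: str) -> list[tuple[str, str]]:
        return [
            (r["ts_utc"], r["message"])
            for r in self._db.execute(
                "SELECT ts_utc, message FROM syslog WHERE task_id=? ORDER BY seq",
                (task_id,),
            )
        ]

    # -- provenance ------------------------------------------------------
    def record_transfer(self, task_id: str, dst_uri: str, sha256: str, nbytes: int) -> None:
        seq = self.next_seq()
        with self._db:
            self._db.execute(
                "INSERT INTO transfers (task_id, dst_uri, sha256, nbytes, seq, ts_utc)"
                " VALUES (?,?,?,?,?,?)",
                (task_id, dst_uri, sha256, nbytes, seq, _now_utc()),
            )

    def outputs_for_task(self, task_id: str) -> list[dict]:
        return [
            {"uri": r["dst_uri"], "sha256": r["sha256"], "nbytes": r["nbytes"]}
            for r in self._db.execute(
                "SELECT * FROM transfers WHERE task_id=? ORDER BY seq", (task_id,)
            )
        ]

    def outputs_for_job(self, job_id: str) -> list[dict]:
        out = []
        for trow in self._db.execute(
            "SELECT id FROM tasks WHERE job_id=? ORDER BY id", (job_id,)
        ):
            out.extend(self.outputs_for_task(trow["id"]))
        return out

    def inputs_for_task(self, task_id: str) -> list[str]:
        return [
            r["uri"]
            for r in self._db.execute(
                "SELECT uri FROM task_inputs WHERE task_id=? ORDER BY rowid", (task_id,)
            )
        ]

    def provenance(self, wf_id: str) -> dict:
        """The complete audit record: every tool, every bound parameter
        value, every input URI, every rendered command, every output
        checksum — sufficient to resubmit the workflow identically."""
        wf = self.workflow(wf_id)
        record = {
            "workflow_id": wf.id,
            "name": wf.name,
            "user": wf.user,
            "metadata": wf.metadata,
            "status": wf.status.value,
            "final": wf.status in (Status.COMPLETE, Status.ERROR),
            "created_utc": wf.created_utc,
            "request": wf.request,
            "jobs": [],
        }
        for job in wf.jobs:
            jrec = {
                "index": job.index,
                "tool": job.tool,
                "tool_spec": job.tool_spec,
                "args": job.args,
                "status": job.status.value,
                "diagnostic": job.diagnostic,
                "tasks": [],
            }
            for task in job.tasks:
                jrec["tasks"].append(
                    {
                        "id": task.id,
                        "command": task.command,
                        "status": task.status.value,
                        "exit_code": task.exit_code,
                        "attempt_count": task.attempt_count,
                        "inputs": self.inputs_for_task(task.id),
                        "outputs": self.outputs_for_task(task.id),
                    }
                )
            record["jobs"].append(jrec)
        return record

    # -- search ----------------------------------------------------------
    def query_workflows(
        self,
        name: str | None = None,
        since: str | None = None,
        until: str | None = None,
        metadata: dict[str, str] | None = None,
    ) -> list[dict]:
        """Conjunction of the provided filters; newest first by default."""
        rows = self._db.execute("SELECT * FROM workflows ORDER BY seq DESC").fetchall()
        out = []
        for r in rows:
            if name is not None and r["name"] != name:
                continue
            if since is not None and r["created_utc"] < since:
                continue
            if until is not None and r["created_utc"] > until:
                continue
            if metadata:
                md = json.loads(r["metadata"])
                if any(md.get(k) != v for k, v in metadata.items()):
                    continue
            out.append(
                {
                    "workflow_id": r["id"],
                    "name": r["name"],
                    "user": r["user"],
                    "status": r["status"],
                    "created_utc": r["created_utc"],
                    "metadata": json.loads(r["metadata"]),
                }
            )
        return out

    # -- credentials -----------------------------------------------------
    def put_credential(self, user: str, backend_id: str, payload: dict, expires_at: float | None) -> None:
        with self._db:
            self._db.execute(
                "INSERT OR REPLACE INTO credentials (user, backend_id, payload, expires_at)"
                " VALUES (?,?,?,?)",
                (user, backend_id, json.dumps(payload), expires_at),
            )

    def get_credential(self, user: str, backend_id: str) -> tuple[dict, float | None] | None:
        row = self._db.execute(
            "SELECT payload, expires_at FROM credentials WHERE user=? AND backend_id=?",
            (user, backend_id),
        ).fetchone()
        if row is None:
            return None
        return json.loads(row["payload"]), row["expires_at"]

    def list_credentials(self, user: str) -> list[tuple[str, dict, float | None]]:
        return [
            (r["backend_id"], json.loads(r["payload"]), r["expires_at"])
            for r in self._db.execute(
                "SELECT * FROM credentials WHERE user=? ORDER BY backend_id", (user,)
            )
        ]

    def delete_credential(self, user: str, backend_id: str) -> None:
        with self._db:
            self._db.execute(
                "DELETE FROM credentials WHERE user=? AND backend_id=?",
                (user, backend_id),
            )

    # -- snapshot / restore ----------------------------------------------
    def snapshot(self, path: str | Path) -> None:
        """Versioned JSON export of the entire state (no plaintext secrets)."""
        dump: dict = {"schema_version": SCHEMA_VERSION, "tables": {}, "meta": {}}
        for r in self._db.execute("SELECT key, value FROM meta"):
            dump["meta"][r["key"]] = r["value"]
        for table in _TABLES:
            rows = self._db.execute(f"SELECT * FROM {table}").fetchall()
            dump["tables"][table] = [dict(r) for r in rows]
        text = json.dumps(dump)
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(text)
        tmp.replace(path)

    @classmethod
    def restore(cls, snapshot_path: str | Path, db_path: str | Path = ":memory:") -> "Store":
        """Load a snapshot into a fresh store; refuses partial/corrupt files."""
        try:
            dump = json.loads(Path(snapshot_path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise SchemaMismatch(f"snapshot unreadable or truncated: {exc}") from exc
        if not isinstance(dump, dict) or "schema_version" not in dump:
            raise SchemaMismatch("snapshot missing schema_version")
        if dump["schema_version"] != SCHEMA_VERSION:
            raise SchemaMismatch(
                f"snapshot schema version {dump['schema_version']},"
                f" this build understands {SCHEMA_VERSION}"
            )
        if set(dump.get("tables", {})) != set(_TABLES):
            raise SchemaMismatch("snapshot table set does not match schema")
        store = cls(db_path)
        with store._db:
            for table in _TABLES:
                store._db.execute(f"DELETE FROM {table}")
                for row in dump["tables"][table]:
                    cols = list(row)
                    store._db.execute(
                        f"INSERT INTO {table} ({','.join(cols)})"
                        f" VALUES ({','.join('?' * len(cols))})",
                        [row[c] for c in cols],
                    )
            for key, value in dump.get("meta", {}).items():
                store._db.execute(
                    "INSERT OR REPLACE INTO meta (key, value) VALUES (?,?)", (key, value)
                )
        store.recover_leases()
        return store

    def deep_equal(self, other: "Store") -> bool:
        for table in _TABLES:
            a = [dict(r) for r in self._db.execute(f"SELECT * FROM {table}")]
            b = [dict(r) for r in other._db.execute(f"SELECT * FROM {table}")]
            a = sorted(a, key=json.dumps)
            b = sorted(b, key=json.dumps)
            if a != b:
                return False
        return True
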