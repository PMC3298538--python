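"""Compute services: leasing, lifecycle stages, failure semantics,
status reporting and syslog."""

from pathlib import Path

import pytest

from benchwork.compute import MockQueueBackend
from benchwork.errors import ContractViolation
from benchwork.model import Status
from benchwork.uris import UriRef


def _write_input(engine, tmp_path, text=">r1\nhello acgt\n", name="x.fa"):
    path = tmp_path / name
    path.write_text(text)
    return f"file://{path}"


def _one_job(engine, tmp_path, tool="upper", text=">r1\nhello acgt\n", args=None):
    uri = _write_input(engine, tmp_path, text)
    doc = {"user": "alice", "jobs": [{"tool": tool, "args": {**(args or {}), "infile": uri}}]}
    return engine.submit_workflow(doc)


# -- leases --------------------------------------------------------------


def test_all_ready_tasks_leased_once(engine, tmp_path):
    wf_id = _one_job(engine, tmp_path)
    engine.advance(wf_id)
    first = engine.poll_ready_tasks()
    assert len(first) == 1
    assert engine.poll_ready_tasks() == []  # exactly-once lease


def test_expired_lease_is_reoffered(engine_factory, tmp_path):
    engine = engine_factory(lease_ttl=0.0)  # lease expires immediately
    wf_id = _one_job(engine, tmp_path)
    engine.advance(wf_id)
    assert len(engine.poll_ready_tasks()) == 1
    assert len(engine.poll_ready_tasks()) == 1  # re-offered after expiry


def test_concurrent_pollers_never_share_a_task(engine, tmp_path):
    for _ in range(3):
        wf_id = _one_job(engine, tmp_path)
        engine.advance(wf_id)
    seen = []
    # simulate competing pollers pulling in turns
    for _ in range(10):
        seen.extend(t.id for t in engine.poll_ready_tasks(limit=1))
    assert len(seen) == len(set(seen)) == 3


# -- lifecycle -----------------------------------------------------------


def test_upper_tool_produces_uppercased_output(engine, tmp_path):
    wf_id = _one_job(engine, tmp_path, text=">r1\nhello\n")
    assert engine.drive(wf_id) == Status.COMPLETE
    outputs = engine.store.outputs_for_job(f"{wf_id}-j0")
    assert len(outputs) == 1
    data = engine.storage.read_bytes(UriRef.parse(outputs[0]["uri"]))
    assert data == b">r1\nHELLO\n"


def test_successful_task_cleans_scratch(engine, tmp_path):
    wf_id = _one_job(engine, tmp_path)
    engine.drive(wf_id)
    task = engine.store.workflow(wf_id).jobs[0].tasks[0]
    assert task.status == Status.COMPLETE
    assert not Path(task.scratch).exists()


def test_fail42_errors_preserves_scratch_captures_stderr(engine, tmp_path):
    wf_id = engine.submit_workflow({"user": "alice", "jobs": [{"tool": "fail42", "args": {}}]})
    assert engine.drive(wf_id) == Status.ERROR
    task = engine.store.workflow(wf_id).jobs[0].tasks[0]
    assert task.status == Status.ERROR
    assert task.exit_code == 42
    scratch = Path(task.scratch)
    assert scratch.exists()  # preserved for diagnosis
    stderr = (scratch / "log" / "stderr.txt").read_text()
    assert "synthetic failure" in stderr
    log = " ".join(m for _, m in engine.store.syslog(task.id))
    assert "exit code 42" in log and "scratch preserved" in log


def test_stage_in_places_both_files_in_scratch(engine, tmp_path):
    (tmp_path / "a.fa").write_text(">a\nAC\n")
    (tmp_path / "a.qual").write_text("30\n")
    doc = {
        "user": "alice",
        "jobs": [
            {
                "tool": "merge",
                "args": {"seq": f"file://{tmp_path}/a.fa", "qual": f"file://{tmp_path}/a.qual"},
            }
        ],
    }
    wf_id = engine.submit_workflow(doc)
    assert engine.drive(wf_id) == Status.COMPLETE
    outputs = engine.store.outputs_for_job(f"{wf_id}-j0")
    merged = engine.storage.read_bytes(UriRef.parse(outputs[0]["uri"]))
    assert merged == b">a\nAC\n30\n"  # both staged files reached the command


def test_nonzero_exit_is_not_retried(engine, tmp_path):
    wf_id = engine.submit_workflow({"user": "alice", "jobs": [{"tool": "fail42", "args": {}}]})
    engine.drive(wf_id)
    task = engine.store.workflow(wf_id).jobs[0].tasks[0]
    assert task.attempt_count == 1  # deterministic failure, one attempt only


# -- mock queue ----------------------------------------------------------


def test_mockq_latency_then_completion(engine_factory, tmp_path):
    engine = engine_factory(
        "mockq-home", compute_backends={"mockq": MockQueueBackend(latency_polls=3)}
    )
    (tmp_path / "s.fa").write_text(">r\nAC\n")
    doc = {
        "user": "alice",
        "jobs": [{"tool": "sleepy", "args": {"infile": f"file://{tmp_path}/s.fa", "delay": "0"}}],
    }
    wf_id = engine.submit_workflow(doc)
    assert engine.drive(wf_id) == Status.COMPLETE


def test_lost_submissions_retried_then_blocked(engine_factory, tmp_path):
    mockq = MockQueueBackend()
    mockq.lose_next = 99  # every attempt vanishes
    engine = engine_factory("lost-home", compute_backends={"mockq": mockq})
    (tmp_path / "s.fa").write_text(">r\nAC\n")
    doc = {
        "user": "alice",
        "jobs": [{"tool": "sleepy", "args": {"infile": f"file://{tmp_path}/s.fa", "delay": "0"}}],
    }
    wf_id = engine.submit_workflow(doc)
    status = engine.drive(wf_id)
    task = engine.store.workflow(wf_id).jobs[0].tasks[0]
    assert status == Status.BLOCKED
    assert task.status == Status.BLOCKED  # blocked, never error
    assert task.attempt_count == 3  # retry policy: three attempts
    # backend recovers -> resume completes without user data loss
    mockq.lose_next = 0
    assert engine.resume(wf_id) == Status.COMPLETE


def test_lost_then_found_recovers_within_retries(engine_factory, tmp_path):
    mockq = MockQueueBackend(latency_polls=0)
    mockq.lose_next = 1  # first submission lost, second lands
    engine = engine_factory("flaky-home", compute_backends={"mockq": mockq})
    (tmp_path / "s.fa").write_text(">r\nAC\n")
    doc = {
        "user": "alice",
        "jobs": [{"tool": "sleepy", "args": {"infile": f"file://{tmp_path}/s.fa", "delay": "0"}}],
    }
    wf_id = engine.submit_workflow(doc)
    assert engine.drive(wf_id) == Status.COMPLETE
    assert engine.store.workflow(wf_id).jobs[0].tasks[0].attempt_count == 2


# -- status reporting ----------------------------------------------------


def test_status_persisted_and_visible_to_advance(engine, tmp_path):
    wf_id = _one_job(engine, tmp_path)
    engine.advance(wf_id)
    (task,) = engine.poll_ready_tasks()
    engine.run_task(task)
    wf = engine.advance(wf_id)  # advance sees the completion
    assert wf.status == Status.COMPLETE


@pytest.mark.parametrize(
    "old,new",
    [
        (Status.COMPLETE, Status.RUNNING),
        (Status.ERROR, Status.READY),
        (Status.PENDING, Status.RUNNING),
        (Status.READY, Status.COMPLETE),
    ],
)
def test_illegal_transitions_are_contract_violations(engine, tmp_path, old, new):
    from benchwork.model import check_transition

    with pytest.raises(ContractViolation):
        check_transition(old, new)


def test_report_status_rejects_complete_to_running(engine, tmp_path):
    wf_id = _one_job(engine, tmp_path)
    engine.drive(wf_id)
    task = engine.store.workflow(wf_id).jobs[0].tasks[0]
    with pytest.raises(ContractViolation):
        engine.report_status(task.id, Status.RUNNING)


def test_syslog_append_only_in_order(engine, tmp_path):
    wf_id = _one_job(engine, tmp_path)
    engine.advance(wf_id)
    task = engine.store.workflow(wf_id).jobs[0].tasks[0]
    for i in range(100):
        engine.report_syslog(task.id, f"message {i}")
    log = [m for _, m in engine.store.syslog(task.id)]
    assert [m for m in log if m.startswith("message ")] == [f"message {i}" for i in range(100)]
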