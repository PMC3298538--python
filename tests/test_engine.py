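"""Engine: submission, dependency resolution, batch fan-out, command
rendering, scheduling rounds and terminal-state rules."""

import pytest

from benchwork.engine import render_command
from benchwork.errors import RenderError, ValidationError
from benchwork.fixtures import make_dataset, make_usecase_workflows
from benchwork.model import Status
from benchwork.registry import FileTypePattern, ParamSpec, ToolSpec
from benchwork.uris import UriRef


# -- render_command ------------------------------------------------------


def _tool(params, program="wc", produces=()):
    return ToolSpec(
        name="wc",
        program=program,
        exec_backend="localexec",
        output_location="file:///tmp/out",
        params=tuple(params),
        produces=tuple(FileTypePattern(p) for p in produces),
    )


def test_render_switch_and_value():
    tool = _tool([ParamSpec(name="infile", switch="-i", mandatory=True, accepts=(FileTypePattern("*.txt"),), source_kind="input-file")])
    assert render_command(tool, {"infile": "a.txt"}) == ["wc", "-i", "a.txt"]


def test_render_unbound_optional_omitted_entirely():
    tool = _tool(
        [
            ParamSpec(name="infile", switch="-i", mandatory=True, accepts=(FileTypePattern("*.txt"),), source_kind="input-file"),
            ParamSpec(name="verbose", switch="-v"),
        ]
    )
    assert render_command(tool, {"infile": "a.txt"}) == ["wc", "-i", "a.txt"]


def test_render_unbound_mandatory_names_param():
    tool = _tool([ParamSpec(name="infile", switch="-i", mandatory=True, accepts=(FileTypePattern("*.txt"),), source_kind="input-file")])
    with pytest.raises(RenderError, match="infile"):
        render_command(tool, {})


def test_render_value_with_space_stays_one_token():
    tool = _tool([ParamSpec(name="label", switch="-l")])
    assert render_command(tool, {"label": "two words"}) == ["wc", "-l", "two words"]


def test_render_program_placeholder_substituted_in_place():
    tool = _tool([ParamSpec(name="mode", switch="")], program="wc --mode={mode}")
    assert render_command(tool, {"mode": "fast"}) == ["wc", "--mode=fast"]


def test_render_declared_order_is_stable():
    tool = _tool(
        [
            ParamSpec(name="b", switch="-b"),
            ParamSpec(name="a", switch="-a"),
        ]
    )
    assert render_command(tool, {"a": "1", "b": "2"}) == ["wc", "-b", "2", "-a", "1"]


# -- submission ----------------------------------------------------------


def test_submit_returns_id_before_any_execution(engine, dataset):
    _, base = dataset
    doc = make_usecase_workflows(f"{base}/seq_000.fa")["genome-annotation"]
    wf_id = engine.submit_workflow(doc)
    wf = engine.store.workflow(wf_id)
    assert wf.status == Status.PENDING  # decoupling: nothing ran yet
    assert all(not j.tasks for j in wf.jobs)


def test_submit_rejects_ungranted_tool_naming_job(engine, dataset):
    _, base = dataset
    doc = {
        "user": "bob",  # bob is only granted "upper"
        "jobs": [
            {"tool": "upper", "args": {"infile": f"{base}/seq_000.fa"}},
            {"tool": "mask", "args": {"infile": {"from_job": 0}}},
        ],
    }
    with pytest.raises(ValidationError) as exc_info:
        engine.submit_workflow(doc)
    assert any("job 1" in d for d in exc_info.value.diagnostics)
    # no partial persistence
    assert engine.store.workflow_ids() == []


def test_submit_rejects_forward_reference(engine):
    doc = {
        "user": "alice",
        "jobs": [{"tool": "mask", "args": {"infile": {"from_job": 0}}}],
    }
    with pytest.raises(ValidationError, match="earlier"):
        engine.submit_workflow(doc)


def test_duplicate_submission_gets_distinct_ids(engine, dataset):
    _, base = dataset
    doc = make_usecase_workflows(f"{base}/seq_000.fa")["genome-annotation"]
    a = engine.submit_workflow(doc)
    b = engine.submit_workflow(doc)
    assert a != b
    assert len(engine.store.workflow_ids()) == 2


def test_missing_mandatory_param_rejected(engine):
    with pytest.raises(ValidationError, match="infile"):
        engine.submit_workflow({"user": "alice", "jobs": [{"tool": "mask", "args": {}}]})


# -- dependency resolution ----------------------------------------------


def _linear_doc(base, n=3):
    jobs = [{"tool": "upper", "args": {"infile": f"{base}/seq_000.fa"}}]
    for i in range(1, n):
        jobs.append({"tool": "mask" if i % 2 else "upper", "args": {"infile": {"from_job": i - 1}}})
    return {"user": "alice", "jobs": jobs}


def test_linear_chain_resolves_one_job_at_a_time(engine, dataset):
    _, base = dataset
    wf_id = engine.submit_workflow(_linear_doc(base, 3))
    assert engine.resolve_ready_jobs(wf_id) == [f"{wf_id}-j0"]
    engine.advance(wf_id)
    for task in engine.poll_ready_tasks(workflow_id=wf_id):
        engine.run_task(task)
    # job 0's tasks are complete; exactly the next job is ready now
    assert engine.resolve_ready_jobs(wf_id) == [f"{wf_id}-j1"]
    engine.advance(wf_id)
    wf = engine.store.workflow(wf_id)
    assert wf.jobs[0].status == Status.COMPLETE
    # a job never comes back as ready once expanded into tasks
    assert engine.resolve_ready_jobs(wf_id) == []


def test_independent_jobs_become_ready_together(engine, dataset):
    _, base = dataset
    doc = {
        "user": "alice",
        "jobs": [
            {"tool": "upper", "args": {"infile": f"{base}/seq_000.fa"}},
            {"tool": "mask", "args": {"infile": {"from_job": 0}}},
            {"tool": "predict", "args": {"infile": {"from_job": 0}}},
        ],
    }
    wf_id = engine.submit_workflow(doc)
    engine.advance(wf_id)
    for task in engine.poll_ready_tasks(workflow_id=wf_id):
        engine.run_task(task)
    ready = engine.resolve_ready_jobs(wf_id)
    assert ready == [f"{wf_id}-j1", f"{wf_id}-j2"]


def test_missing_input_file_blocks_not_errors(engine, tmp_path):
    doc = {
        "user": "alice",
        "jobs": [{"tool": "upper", "args": {"infile": f"file://{tmp_path}/absent.fa"}}],
    }
    wf_id = engine.submit_workflow(doc)
    assert engine.resolve_ready_jobs(wf_id) == []
    wf = engine.store.workflow(wf_id)
    assert wf.jobs[0].status == Status.BLOCKED
    assert "missing" in wf.jobs[0].diagnostic
    # the file appears -> the job resumes on a later round
    (tmp_path / "absent.fa").write_text(">r\nACGT\n")
    assert engine.drive(wf_id) == Status.COMPLETE


# -- batch fan-out -------------------------------------------------------


@pytest.mark.parametrize("n", [1, 5, 14])
def test_single_batch_param_one_task_per_matching_file(engine, tmp_path, n):
    base = f"file://{tmp_path}/batch{n}"
    make_dataset(engine.storage, base, seed=n, n_files=n)
    doc = {"user": "alice", "jobs": [{"tool": "upper", "args": {"infile": f"{base}/*.fa"}}]}
    wf_id = engine.submit_workflow(doc)
    engine.advance(wf_id)
    wf = engine.store.workflow(wf_id)
    assert len(wf.jobs[0].tasks) == n


def test_non_batch_all_literal_job_is_one_task(engine):
    wf_id = engine.submit_workflow({"user": "alice", "jobs": [{"tool": "fail42", "args": {}}]})
    engine.advance(wf_id)
    wf = engine.store.workflow(wf_id)
    assert len(wf.jobs[0].tasks) == 1


def test_two_batchable_params_pair_by_name(engine, tmp_path):
    base = f"file://{tmp_path}/paired"
    make_dataset(engine.storage, base, seed=3, n_files=3, paired=True)
    doc = {
        "user": "alice",
        "jobs": [
            {"tool": "merge", "args": {"seq": f"{base}/*.fa", "qual": f"{base}/*.qual"}}
        ],
    }
    wf_id = engine.submit_workflow(doc)
    engine.advance(wf_id)
    wf = engine.store.workflow(wf_id)
    assert len(wf.jobs[0].tasks) == 3
    for i, task in enumerate(wf.jobs[0].tasks):
        # commands carry the paired basenames: seq_00i.fa with seq_00i.qual
        joined = " ".join(task.command)
        assert f"seq_{i:03d}.fa" in joined and f"seq_{i:03d}.qual" in joined


def test_zero_match_batch_is_job_error_with_diagnostic(engine, tmp_path):
    base = f"file://{tmp_path}/nofa"
    engine.storage.mkdir(UriRef.parse(base))
    doc = {"user": "alice", "jobs": [{"tool": "upper", "args": {"infile": f"{base}/*.fa"}}]}
    wf_id = engine.submit_workflow(doc)
    engine.advance(wf_id)
    wf = engine.store.workflow(wf_id)
    assert wf.jobs[0].status == Status.ERROR
    assert "no input satisfies pattern" in wf.jobs[0].diagnostic


# -- advance / terminal rules -------------------------------------------


def test_workflow_complete_iff_all_jobs_complete(engine, dataset):
    _, base = dataset
    wf_id = engine.submit_workflow(_linear_doc(base, 3))
    assert engine.drive(wf_id) == Status.COMPLETE
    wf = engine.store.workflow(wf_id)
    assert all(j.status == Status.COMPLETE for j in wf.jobs)


def test_one_job_error_makes_workflow_error(engine, dataset):
    _, base = dataset
    doc = {
        "user": "alice",
        "jobs": [
            {"tool": "upper", "args": {"infile": f"{base}/seq_000.fa"}},
            {"tool": "fail42", "args": {}},
        ],
    }
    wf_id = engine.submit_workflow(doc)
    assert engine.drive(wf_id) == Status.ERROR
    wf = engine.store.workflow(wf_id)
    assert wf.jobs[0].status == Status.COMPLETE  # sibling allowed to finish
    assert wf.jobs[1].status == Status.ERROR


def test_downstream_of_errored_job_fails_with_upstream_diagnostic(engine, dataset):
    _, base = dataset
    doc = {
        "user": "alice",
        "jobs": [
            {"tool": "fail42", "args": {}},
            {"tool": "upper", "args": {"infile": {"from_job": 0}}},
        ],
    }
    wf_id = engine.submit_workflow(doc)
    assert engine.drive(wf_id) == Status.ERROR
    wf = engine.store.workflow(wf_id)
    assert wf.jobs[1].status == Status.ERROR
    assert "upstream" in wf.jobs[1].diagnostic


def test_advance_is_idempotent_on_terminal_workflow(engine, dataset):
    _, base = dataset
    wf_id = engine.submit_workflow(_linear_doc(base, 2))
    engine.drive(wf_id)
    before = engine.store.provenance(wf_id)
    engine.advance(wf_id)
    engine.advance(wf_id)
    assert engine.store.provenance(wf_id) == before


def test_two_runs_produce_byte_identical_outputs(engine, tmp_path, dataset):
    _, base = dataset
    doc = make_usecase_workflows(f"{base}/seq_001.fa")["genome-annotation"]
    digests = []
    for _ in range(2):
        wf_id = engine.submit_workflow(doc)
        assert engine.drive(wf_id) == Status.COMPLETE
        outputs = []
        for job in engine.store.workflow(wf_id).jobs:
            for task in job.tasks:
                outputs.extend(
                    (UriRef.parse(o["uri"]).basename, o["sha256"])
                    for o in engine.store.outputs_for_task(task.id)
                )
        digests.append(sorted(outputs))
    assert digests[0] == digests[1]
    assert len(digests[0]) > 0
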