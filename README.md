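# benchwork

A desk-scale scientific workflow engine for chaining command-line analysis
tools over files spread across heterogeneous storage, written for
bioinformatics-style pipelines (mask repeats → predict genes → reformat;
extract ORFs → classify receptors; proteomics search chains) but
domain-agnostic by construction.

Who it is for: groups that need reproducible multi-step pipelines with
batch fan-out, audit trails and resumable execution, without adopting a
cluster-scale deployment. Everything runs in one process against a
single-file database; storage and compute resources are pluggable
backends addressed by URI scheme.

## What the engine does

* **Declarative tools.** A tool is a config record — command template,
  parameters, accepted/produced *file types* (unix-style filename globs,
  e.g. `*.fa`), execution backend, output location. Adding a tool is a
  config edit, never a code change.
* **Dynamic dependency resolution.** A workflow is an ordered list of
  jobs; a job may declare that a parameter takes "the output of job *k*"
  before those files exist. A job becomes ready once every referenced
  job has finished and every referenced input file is present; only then
  is it expanded into concrete tasks.
* **Batch fan-out and input pairing.** A batchable parameter matching
  *n* files expands into *n* tasks. When two batchable parameters take
  different file types (`*.fa` with `*.qual`), files are paired by
  minimizing the total Levenshtein edit distance between their names —
  an exact minimum-cost assignment for desk-sized batches, with
  deterministic lexicographic tie-breaking.
* **Task lifecycle.** Each task runs stage-in → execute → monitor →
  stage-out → cleanup against pluggable storage (`file://`, `mem://`)
  and compute (`localexec`, `mockq`) backends, with captured
  stdout/stderr, append-only syslog, and success defined as exit code 0.
* **Blocked, not failed.** Transient user-fixable faults — a missing
  credential, an unreachable backend, an input that has not appeared —
  park work in a resumable `blocked` state; only real failures become
  `error`. Every workflow driven to the end is `complete` or `error`.
* **Encrypted credentials.** Per-backend secrets are stored AES-encrypted
  under a password-derived key (PBKDF2) with authenticated ciphertexts,
  decrypted only into a RAM cache at login, and never persisted in
  plaintext.
* **Crash-safe resume.** Every state change is committed to an embedded
  SQLite store before it is acknowledged; stage markers let a restarted
  engine resume each task at its last incomplete lifecycle stage without
  re-running completed commands. Versioned JSON snapshots export/restore
  the whole state.
* **Provenance.** Each workflow's record — tools as-run, bound
  parameters, input URIs, rendered commands, output checksums — is
  queryable (name/date/metadata) and sufficient to resubmit the workflow
  and reproduce its outputs byte-for-byte.

## Worked example

```bash
# emit the synthetic toolkit (deterministic stand-in tools), a seeded
# dataset and three ready-made workflow documents into ./sandbox
benchwork --home ./bw fixtures ./sandbox
benchwork --home ./bw login --user alice     # prompts for a password
benchwork --home ./bw submit ./sandbox/workflows/genome-annotation.json
benchwork --home ./bw work
benchwork --home ./bw jobs
```

A session looks like:

```
$ benchwork --home ./bw submit ./sandbox/workflows/genome-annotation.json
wf-d072a34823b0
$ benchwork --home ./bw work
wf-d072a34823b0	complete
$ benchwork --home ./bw status wf-d072a34823b0
wf-d072a34823b0	genome-annotation	complete
  job 0 upper complete
    task wf-d072a34823b0-j0-t0000 complete
  job 1 mask complete
    task wf-d072a34823b0-j1-t0000 complete
  job 2 predict complete
    task wf-d072a34823b0-j2-t0000 complete
  job 3 tognff complete
    task wf-d072a34823b0-j3-t0000 complete
$ benchwork --home ./bw fetch wf-d072a34823b0 ./results
fetched 4 file(s) to results
```

`submit` printed the new workflow id and returned immediately (submission
is decoupled from processing); `work` then drove the four chained jobs —
normalize case, mask vowels (the repeat-masker stand-in), extract
uppercase runs (the gene-predictor stand-in), reformat to a tab table —
each consuming the previous job's output, to the terminal `complete`
state. `benchwork fetch wf-75a68c3f2e91 ./results` copies the outputs
out, verifying every file against the checksums recorded in provenance.

The same flows are available as a library:

```python
from benchwork import build_engine
from benchwork.fixtures import make_toolkit, make_dataset, make_usecase_workflows

toolkit = make_toolkit("sandbox/toolkit")
engine = build_engine("sandbox/home", toolkit.config_path)
make_dataset(engine.storage, "file:///tmp/data", seed=7, n_files=14)
wf_id = engine.submit_workflow(
    {"user": "alice",
     "jobs": [{"tool": "upper", "args": {"infile": "file:///tmp/data/*.fa"}}]})
engine.drive(wf_id)            # 14 matching files -> 14 tasks -> complete
```

File formats, the URI grammar and the config/workflow schemas are
documented in `docs/formats.md`; the model and its design decisions in
`docs/methods.md`.

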