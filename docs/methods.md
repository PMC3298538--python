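# Methods

## The execution model

benchwork models an analysis pipeline at three levels. A **workflow** is
the user-submitted ordered list of **jobs**, each one tool invocation;
file dependencies between jobs are declared by reference ("parameter
`infile` takes the output of job 0"), not by filename, because the files
do not exist at submission time. When every referenced job has finished
and every referenced input file is present on its storage backend, the
job is expanded into **tasks**, each a single concrete command execution
with its own stage-in list, rendered argument vector and stage-out
destination.

Submission is decoupled from processing: `submit_workflow` validates
against the registry, persists the request and returns an id; nothing
has run when it returns. `advance` performs one scheduling round —
fold task statuses into jobs, fail jobs whose upstream errored, expand
newly ready jobs — and is idempotent when nothing changed. `drive`
alternates rounds with the pull-based task queue until the workflow is
terminal (`complete` iff all jobs completed; `error` once all jobs are
terminal and at least one failed) or stuck on a transient fault
(`blocked`, resumable).

### File types and batch fan-out

Whether a file can satisfy a parameter is decided by matching its
basename, case-sensitively, against the parameter's glob patterns
(`*`, `?`, `[...]`; no `**`, no path separators — the narrowest common
dialect, chosen because "unix-style filename matching" is ambiguous
across shells). A batchable parameter matching *n* files expands into
*n* tasks. Zero matches are a job *error* with the diagnostic
`no input satisfies pattern`: silent empty fan-out would hide user
mistakes, which we judged worse than failing a legitimate empty batch.

With two batchable parameters of different types, each file of one type
must be grouped with its counterpart of the other. The pairing minimizes
the total Levenshtein distance (unit-cost edit distance) between paired
basenames. For groups up to 12 the optimum is computed exactly (the
rectangular assignment problem, solved with the Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`); among equally cheap pairings
the lexicographically smallest pair list is selected by greedy pair
fixing, so results are fully deterministic. Above 12 a greedy
nearest-pair heuristic with the same tie-break is used — batches that
need name-pairing are small in practice, and the exact path covers the
sizes the engine targets. When group sizes differ, `min(|A|,|B|)` pairs
are formed and the leftovers are *reported* on the job (they fail the
job only if a mandatory parameter ends up unfilled).

More than two batchable parameters on one tool is rejected as a job
error: no pairing criterion generalizes unambiguously, and no use case
required it.

### Status machine

Tasks move through `pending → ready → staging_in → running →
staging_out → complete`; any non-terminal state may move to `blocked`
(transient fault) or `error`; `blocked` resumes to its prior point in
the pipeline; `error` and `complete` are terminal. Transitions are
enforced in the persistence layer — an illegal move raises a contract
violation, a bug surface rather than a user error. Job and workflow
statuses are derived from their children each round, not transitioned
independently.

The blocked/error distinction is load-bearing: missing credentials,
unreachable backends and not-yet-present input files can only ever
produce `blocked` (this is property-tested), so user intervention plus
`resume` always suffices to continue without loss; only a nonzero exit
code — deterministic by assumption, hence never retried — or an
exhausted batch produces `error`.

### Task lifecycle and exactly-once execution

The runner persists a stage marker after each completed lifecycle stage
(`staged_in`, `executed` with the exit code, `staged_out`, `done`). A
resumed task restarts at its first incomplete stage: in particular a
task whose exit code is already recorded stages out without re-running
the command. Recovery granularity is therefore the lifecycle stage (a
transfer interrupted mid-copy is redone from the start of that stage and
overwrites its partial destination); byte-level transfer resume was
deliberately left out. Transient compute faults (a lost submission) are
retried up to 3 attempts with exponential backoff and then block; the
retry budget is per run, while the stored attempt count accumulates
across resumes for the audit trail.

On success the scratch area (`<work_root>/<workflow>/<task>/` with
`in/`, `out/`, `log/`) is removed; on failure it is preserved and
referenced from the task's syslog, with captured stdout/stderr alongside.

## Storage and streaming copy

All file operations dispatch purely on URI scheme through a router;
registering a new scheme touches nothing else. Copy streams bounded
chunks (default 4 MiB, hard ceiling 8 MiB) from a producer iterator
straight into the destination writer while hashing: the observable
contract — no intermediate spool file, bounded in-flight bytes, SHA-256
recorded in the transfer report — is what the kernel-FIFO device in
larger deployments achieves, realized here as an in-process
producer/consumer channel. Copies overwrite existing destinations so
stage-out is idempotent under resume; a copy onto the same location is
rejected. Rename is not a backend primitive and is provided as
copy+delete.

## Credentials

Secrets are encrypted per record with AES-256-CTR under a key derived
from the user's password (PBKDF2-HMAC-SHA256, fresh 16-byte salt and
nonce per record) and authenticated with HMAC-SHA256 over the full
record, encrypt-then-MAC; wrong passwords and any ciphertext tampering
fail authentication without emitting plaintext. The AES core is
implemented in-package (tables generated from the GF(2⁸) arithmetic)
and verified against the published known-answer vectors for all three
key sizes; it only ever touches credential-sized payloads. Decrypted
secrets live exclusively in a session RAM cache, cleared on
logout/shutdown and never serialized — snapshots are scanned in tests
to prove no plaintext escapes.

The KDF work factor is stored per record. The default is 200 000
iterations; the test-suite and acceptance harness construct vaults with
a reduced factor (10³ or less), chosen up front, because every property
they exercise — round-trip identity, tamper detection, blocking — is
invariant to the iteration count. Per-record optional TTLs implement
credential expiry; an expired record behaves as not stored. The vault
password is treated as the application login password, but the API keeps
the two separable.

## Persistence, snapshots, provenance

A single-file SQLite database is the system of record; every mutation
commits before it is acknowledged, which gives the write-ahead property
(a workflow acknowledged by submit survives an immediate crash) for
free. Ready tasks are leased atomically from the same store — each
handed out once until its lease expires without progress — which is the
in-process realization of the decoupled submission/processing queue; a
restarted engine clears stale leases and re-offers in-flight work.
Snapshots are versioned JSON exports of the full state including task
continuations (stage markers, attempt counts); truncated or
version-mismatched snapshots are refused whole. Timestamps are UTC,
ordered by a global monotonic sequence number so audit ordering cannot
depend on clock skew.

Result files never live in the store: only URIs and SHA-256 checksums
are recorded, so data stays on the storage resources it belongs to.
Provenance for each workflow — tools as-run, bound arguments, input
URIs, rendered commands, output checksums — is complete enough that
resubmitting the recorded request reproduces byte-identical outputs on
deterministic tools, and this is tested.

## The synthetic toolkit and what the tests show

The fixture tools are deterministic text transforms over pseudo-FASTA
files (documented in `benchwork.fixtures`), chosen so expected outputs
are computable by independent oracles and the whole suite is hermetic.
They emulate the *shape* of real pipelines — multi-step chains, fan-out
over record files, a simulated batch queue with dispatch latency, fault
injection — but not their substance: no biological realism, no large
binaries, no network protocols, no real scheduler semantics beyond the
submit/poll/cancel contract. Passing tests therefore demonstrate the
engine's orchestration guarantees (ordering, cardinality, determinism,
resume, blocking), not the scientific validity of any real tool chain,
and say nothing about throughput at cluster scale.

Problem sizes in the suite and acceptance harness are the package's
desk-scale design points: three use-case chains of 3–4 jobs, fan-out up
to 100 files, pairing groups to 6 names (against exhaustive search),
one 100 MiB streaming transfer, 1 000 credential round trips, and 50
seeded trials each for the randomized-DAG ordering check and the
kill-at-random-checkpoint crash/resume fuzz over a 5-job workflow.
Crash points are the persisted stage boundaries — the granularity at
which the engine makes durability promises; an OS-level kill between
boundaries re-runs at most the one incomplete stage.

## Numerical and degenerate-input choices

Globs are validated (non-empty, no `/`, balanced `[...]`) before use.
Empty files copy to empty files with the hash of the empty string.
Levenshtein is implemented with the two-row dynamic program; ties in
pairing are broken lexicographically everywhere. Command rendering never
passes through a shell: values stay single argv tokens verbatim, which
is also the injection-safety decision — there is no quoting layer to get
wrong. Unknown config keys, duplicate names, dangling references and
forward job references are all rejected at load/submit time with
messages naming the offender.

## Known limitations

Single-process, single-user-at-a-time engine; no real SSH/S3/cluster
drivers (the plug-in contracts and mock implementations stand in); no
conditionals, loops or sub-workflows; no cross-workflow scheduling
policy (scheduling belongs to the external resource by design); rename
is copy+delete; pairing above 12 names is heuristic; stage-level (not
byte-level) transfer resume.
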