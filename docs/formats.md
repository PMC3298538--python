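# File formats, URI grammar and document schemas

## URI grammar

Every location the engine touches is a URI; the scheme selects the
backend, so the rest of the system never knows how bytes are stored.

```
uri     = scheme "://" [ user "@" ] host [ path ]
scheme  = ALPHA *( ALPHA / DIGIT / "+" / "-" / "." )
user    = 1*( %x21-7E except "@" and "/" )
host    = *( %x21-7E except "/" )
path    = "/" *( segment "/" ) [ segment ]      ; absolute
segment = 1*( %x21-7E except "/" )              ; "." and ".." forbidden
```

Bundled schemes:

* `file:///abs/path` — local filesystem (empty host);
* `mem://store/path` — in-memory named store `store` (hermetic tests,
  instrumented backends);
* any other scheme may be registered at runtime
  (`StorageRouter.register(scheme, driver, ...)`), e.g. `ssh://user@host/p`
  for a third-party driver.

Parsing normalizes the path (duplicate and trailing slashes collapse);
`render()` and `parse()` round-trip exactly. `.`/`..` segments are
rejected outright rather than resolved.

## Registry config

One JSON (canonical) or YAML document; schema is strict — unknown keys
are rejected. `schema_version` must be `1`.

```jsonc
{
  "schema_version": 1,
  "backends": [
    // kind: "storage" | "compute"; scheme selects the driver plug-in
    {"id": "localexec", "kind": "compute", "scheme": "localexec"},
    {"id": "localfs",   "kind": "storage", "scheme": "file",
     "endpoint": "", "requires_credential": false, "reachable": true}
  ],
  "tools": [
    {
      "name": "wordcount",              // unique
      "program": "wc",                  // whitespace-split template; may
                                        // embed {param} placeholders
      "exec_backend": "localexec",      // must name a compute backend
      "output_location": "file:///results/{workflow_id}/j{job_index}_{tool}",
      "params": [
        {"name": "infile",
         "switch": "-i",                // token emitted before the value
         "mandatory": true,
         "accepts": ["*.txt"],          // file types (basename globs)
         "batchable": false,            // true => one task per match
         "source_kind": "input-file"}   // user-literal | input-file |
                                        // previous-job-output
      ],
      "produces": ["*.out"]             // which scratch files stage out
    }
  ],
  "users": [
    {"name": "alice", "tools": ["wordcount"], "backends": ["localexec", "localfs"]}
  ]
}
```

`output_location` placeholders: `{workflow_id}`, `{workflow_name}`,
`{job_index}`, `{job_id}`, `{tool}`, `{user}`, `{task_id}`.

A complete nine-tool example is emitted by
`benchwork fixtures <dest>` (or `benchwork.fixtures.make_toolkit`).

## Workflow document

```jsonc
{
  "name": "run-A",                      // optional; generated if absent
  "user": "alice",
  "metadata": {"project": "x"},         // arbitrary searchable tags
  "jobs": [
    {"tool": "upper",
     "args": {"infile": "file:///data/*.fa"}},          // glob fan-out
    {"tool": "mask",
     "args": {"infile": {"from_job": 0}}},              // dependency ref
    {"tool": "tognff",
     "args": {"infile": {"from_job": 1, "pattern": "*.masked.fa"}}}
  ]
}
```

Argument forms, interpreted per the parameter's spec:

* plain string — a literal for free-form parameters, a URI for file
  parameters (the basename may contain `*`, `?`, `[...]`);
* `{"literal": ...}` / `{"uri": ...}` — explicit forms;
* `{"from_job": k, "pattern": optional-glob}` — the staged-out outputs
  of job `k` (0-based, strictly earlier), filtered by the override
  pattern or the parameter's accepted file types.

## Task hand-off record

Tasks handed to the compute layer carry the fully rendered argument
vector, the stage-in list `(source URI, staged basename)`, the stage-out
destination and `produces` filter; status and syslog reporting go back
through `Engine.report_status` / `Engine.report_syslog`. Captured
stdout/stderr live as plain text files in the task's scratch `log/`
area (preserved on failure).

## Provenance export

`Store.provenance(workflow_id)` returns a JSON document with the
original request, per-job tool specs as-run, bound arguments and
per-task rendered commands, input URIs and output `{uri, sha256,
nbytes}` records — sufficient to resubmit the workflow identically.
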