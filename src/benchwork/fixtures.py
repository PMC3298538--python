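"""Synthetic toolkit and data generator.

Real pipelines chain programs like a repeat masker, a gene predictor, a
GFF reformatter, an ORF extractor and a receptor classifier over molecular
sequence files.  Those binaries would break hermeticity, so this module
emits small deterministic stand-ins with documented text-transform
semantics (each a pure function of its input files and arguments), plus a
registry config wiring them to the bundled ``localexec`` and ``mockq``
compute backends, seeded pseudo-FASTA datasets, and three ready-made
workflow documents exercising linear chaining, batch fan-out and
mixed-backend execution.

Stand-in semantics (the oracle for every expected output in the tests):

===========  ==================================================================
``upper``    sequence lines uppercased -> ``<stem>.upper.fa``
``mask``     uppercase vowels (AEIOU) lowercased -> ``<stem>.masked.fa``
             (repeat-masker stand-in: "masks" part of the sequence)
``predict``  maximal runs of uppercase letters of length >= k (default 3),
             one record per run with start/end -> ``<stem>.pred.fa``
``tognff``   any record file -> tab table ``name<TAB>start<TAB>end<TAB>seq``
             -> ``<stem>.tab``
``orfs``     splits a multi-record file into one ``<stem>_NNN.orf`` file per
             record with sequence length >= m (default 1)
``classify`` keeps records whose sequence contains a motif (default ``GATC``)
             -> ``<stem>.hit.fa`` (always written, possibly empty)
``merge``    concatenates a sequence file and a quality file
             -> ``<stemA>.merged.txt``
``sleepy``   sleeps ``-s`` seconds (default 0.05) then copies the input
             -> ``<stem>.slept.fa``
``fail42``   always exits with status 42 (failure-path fixture)
===========  ==================================================================

Every tool appends start/end lines to the file named by the ``BW_LEDGER``
environment variable (when set): ``tool<TAB>task<TAB>phase<TAB>monotonic_ns
<TAB>nonce``.  The ledger is the oracle for exactly-once execution and for
dependency-ordering checks; it never influences tool output.
"""

from __future__ import annotations

import hashlib
import json
import random
import sys
from dataclasses import dataclass, field
from pathlib import Path

from .model import WorkflowRequest
from .storage import StorageRouter
from .uris import UriRef

_PROLOGUE = '''\
import os, sys, time, uuid


def ledger(tool, phase):
    path = os.environ.get("BW_LEDGER")
    if not path:
        return
    with open(path, "a") as fh:
        fh.write("%s\\t%s\\t%s\\t%d\\t%s\\n" % (
            tool, os.environ.get("BW_TASK", "-"), phase,
            time.monotonic_ns(), uuid.uuid4().hex))


def read_records(path):
    name, seq = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\\n")
            if line.startswith(">"):
                if name is not None:
                    yield name, seq
                name, seq = line[1:], []
            else:
                seq.append(line)
    if name is not None:
        yield name, seq


def stem(path):
    base = os.path.basename(path)
    return base.rsplit(".", 1)[0] if "." in base else base
'''

_SCRIPTS = {
    "upper": '''\
ledger("upper", "start")
src = sys.argv[1]
with open(stem(src) + ".upper.fa", "w") as out:
    for name, seq in read_records(src):
        out.write(">%s\\n" % name)
        for line in seq:
            out.write(line.upper() + "\\n")
ledger("upper", "end")
''',
    "mask": '''\
ledger("mask", "start")
src = sys.argv[1]
table = str.maketrans("AEIOU", "aeiou")
with open(stem(src) + ".masked.fa", "w") as out:
    for name, seq in read_records(src):
        out.write(">%s\\n" % name)
        for line in seq:
            out.write(line.translate(table) + "\\n")
ledger("mask", "end")
''',
    "predict": '''\
ledger("predict", "start")
args = sys.argv[1:]
k = 3
if "-k" in args:
    i = args.index("-k")
    k = int(args[i + 1])
    del args[i:i + 2]
src = args[0]
with open(stem(src) + ".pred.fa", "w") as out:
    for name, seq in read_records(src):
        text = "".join(seq)
        run_start, runs = None, []
        for i, ch in enumerate(text + "."):
            if ch.isupper():
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None and i - run_start >= k:
                    runs.append((run_start, i))
                run_start = None
        for n, (a, b) in enumerate(runs, start=1):
            out.write(">%s_r%d %d %d\\n%s\\n" % (name, n, a + 1, b, text[a:b]))
ledger("predict", "end")
''',
    "tognff": '''\
ledger("tognff", "start")
src = sys.argv[1]
with open(stem(src) + ".tab", "w") as out:
    for name, seq in read_records(src):
        text = "".join(seq)
        fields = name.split()
        if len(fields) == 3 and fields[1].isdigit() and fields[2].isdigit():
            out.write("%s\\t%s\\t%s\\t%s\\n" % (fields[0], fields[1], fields[2], text))
        else:
            out.write("%s\\t1\\t%d\\t%s\\n" % (fields[0], len(text), text))
ledger("tognff", "end")
''',
    "orfs": '''\
ledger("orfs", "start")
args = sys.argv[1:]
m = 1
if "-m" in args:
    i = args.index("-m")
    m = int(args[i + 1])
    del args[i:i + 2]
src = args[0]
n = 0
for name, seq in read_records(src):
    if len("".join(seq)) < m:
        continue
    n += 1
    with open("%s_%03d.orf" % (stem(src), n), "w") as out:
        out.write(">%s\\n" % name)
        for line in seq:
            out.write(line + "\\n")
ledger("orfs", "end")
''',
    "classify": '''\
ledger("classify", "start")
args = sys.argv[1:]
motif = "GATC"
if "--motif" in args:
    i = args.index("--motif")
    motif = args[i + 1]
    del args[i:i + 2]
src = args[0]
with open(stem(src) + ".hit.fa", "w") as out:
    for name, seq in read_records(src):
        if motif in "".join(seq):
            out.write(">%s\\n" % name)
            for line in seq:
                out.write(line + "\\n")
ledger("classify", "end")
''',
    "merge": '''\
ledger("merge", "start")
a, b = sys.argv[1], sys.argv[2]
with open(stem(a) + ".merged.txt", "w") as out:
    for path in (a, b):
        with open(path) as fh:
            out.write(fh.read())
ledger("merge", "end")
''',
    "sleepy": '''\
ledger("sleepy", "start")
args = sys.argv[1:]
delay = 0.05
if "-s" in args:
    i = args.index("-s")
    delay = float(args[i + 1])
    del args[i:i + 2]
src = args[0]
time.sleep(delay)
with open(src) as fh, open(stem(src) + ".slept.fa", "w") as out:
    out.write(fh.read())
ledger("sleepy", "end")
''',
    "fail42": '''\
ledger("fail42", "start")
sys.stderr.write("synthetic failure: this tool always fails\\n")
ledger("fail42", "end")
sys.exit(42)
''',
}

#: tools wired to the simulated batch queue; the rest run on localexec
MOCKQ_TOOLS = ("classify", "sleepy")


@dataclass
class ToolkitManifest:
    dest: Path
    bin_dir: Path
    config_path: Path
    config: dict


def make_toolkit(dest: str | Path) -> ToolkitManifest:
    """Emit the stand-in tool scripts and a registry config under *dest*."""
    dest = Path(dest).resolve()  # tool/program paths must not depend on cwd
    bin_dir = dest / "bin"
    bin_dir.mkdir(parents=True, exist_ok=True)
    for name, body in _SCRIPTS.items():
        (bin_dir / f"{name}.py").write_text(_PROLOGUE + "\n" + body)

    results = f"file://{dest}/results/{{workflow_id}}/j{{job_index}}_{{tool}}"
    py = sys.executable

    def tool(name, params, produces, backend=None):
        return {
            "name": name,
            "program": f"{py} {bin_dir}/{name}.py",
            "exec_backend": backend or ("mockq" if name in MOCKQ_TOOLS else "localexec"),
            "output_location": results,
            "params": params,
            "produces": produces,
        }

    def infile(accepts, batchable=True):
        return {
            "name": "infile",
            "switch": "",
            "mandatory": True,
            "accepts": accepts,
            "batchable": batchable,
            "source_kind": "input-file",
        }

    config = {
        "schema_version": 1,
        "backends": [
            {"id": "localexec", "kind": "compute", "scheme": "localexec"},
            {"id": "mockq", "kind": "compute", "scheme": "mockq"},
            {"id": "localfs", "kind": "storage", "scheme": "file"},
            {"id": "memdata", "kind": "storage", "scheme": "mem"},
        ],
        "tools": [
            tool("upper", [infile(["*.fa"])], ["*.upper.fa"]),
            tool("mask", [infile(["*.fa"])], ["*.masked.fa"]),
            tool(
                "predict",
                [
                    infile(["*.fa"]),
                    {"name": "minrun", "switch": "-k", "mandatory": False},
                ],
                ["*.pred.fa"],
            ),
            tool("tognff", [infile(["*.fa", "*.tab"])], ["*.tab"]),
            tool(
                "orfs",
                [
                    infile(["*.fa"]),
                    {"name": "minlen", "switch": "-m", "mandatory": False},
                ],
                ["*.orf"],
            ),
            tool(
                "classify",
                [
                    infile(["*.orf"]),
                    {"name": "motif", "switch": "--motif", "mandatory": False},
                ],
                ["*.hit.fa"],
            ),
            tool(
                "merge",
                [
                    {
                        "name": "seq",
                        "switch": "",
                        "mandatory": True,
                        "accepts": ["*.fa"],
                        "batchable": True,
                        "source_kind": "input-file",
                    },
                    {
                        "name": "qual",
                        "switch": "",
                        "mandatory": True,
                        "accepts": ["*.qual"],
                        "batchable": True,
                        "source_kind": "input-file",
                    },
                ],
                ["*.merged.txt"],
            ),
            tool(
                "sleepy",
                [
                    infile(["*.fa"]),
                    {"name": "delay", "switch": "-s", "mandatory": False},
                ],
                ["*.slept.fa"],
            ),
            tool("fail42", [], []),
        ],
        "users": [
            {
                "name": "alice",
                "tools": [
                    "upper", "mask", "predict", "tognff", "orfs",
                    "classify", "merge", "sleepy", "fail42",
                ],
                "backends": ["localexec", "mockq", "localfs", "memdata"],
            },
            {"name": "bob", "tools": ["upper"], "backends": ["localexec", "localfs"]},
        ],
    }
    config_path = dest / "registry.json"
    config_path.write_text(json.dumps(config, indent=2))
    return ToolkitManifest(dest=dest, bin_dir=bin_dir, config_path=config_path, config=config)


# ---------------------------------------------------------------------------
# datasets

_ALPHABET = "ACGT"


@dataclass
class FixtureDataset:
    seed: int
    base_uri: str
    entries: list[tuple[str, int, str]] = field(default_factory=list)  # (name, size, sha256)

    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]


def _record(rng: random.Random, name: str, length: int) -> str:
    seq = "".join(rng.choice(_ALPHABET) for _ in range(length))
    lines = [seq[i : i + 60] for i in range(0, len(seq), 60)]
    return f">{name}\n" + "\n".join(lines) + "\n"


def make_dataset(
    storage: StorageRouter,
    base_uri: str | UriRef,
    seed: int,
    n_files: int,
    size_range: tuple[int, int] = (120, 260),
    paired: bool = False,
) -> FixtureDataset:
    """Write *n_files* seeded pseudo-FASTA files under *base_uri*.

    Regeneration from the same seed is byte-identical.  ``paired=True``
    additionally writes a ``.qual`` file with a matching stem per ``.fa``
    file (for input-pairing scenarios).
    """
    base = UriRef.parse(base_uri) if isinstance(base_uri, str) else base_uri
    rng = random.Random(seed)
    storage.mkdir(base)
    dataset = FixtureDataset(seed=seed, base_uri=base.render())
    for i in range(n_files):
        name = f"seq_{i:03d}.fa"
        n_records = rng.randint(1, 3)
        text = "".join(
            _record(rng, f"rec{i:03d}_{r}", rng.randint(*size_range))
            for r in range(n_records)
        )
        data = text.encode()
        storage.write_bytes(base.join(name), data)
        dataset.entries.append((name, len(data), hashlib.sha256(data).hexdigest()))
        if paired:
            qual_name = f"seq_{i:03d}.qual"
            qual = "".join(
                f"{rng.randint(2, 40)}\n" for _ in range(40)
            ).encode()
            storage.write_bytes(base.join(qual_name), qual)
            dataset.entries.append(
                (qual_name, len(qual), hashlib.sha256(qual).hexdigest())
            )
    return dataset


# ---------------------------------------------------------------------------
# use-case workflows

def make_usecase_workflows(input_uri: str, user: str = "alice") -> dict[str, dict]:
    """Three workflow documents mirroring typical analysis chains.

    * ``genome-annotation`` — four linearly chained jobs (normalize, mask
      repeats, predict genes, reformat to a tab table), each consuming the
      previous job's output.
    * ``orf-screen`` — extract ORFs into many per-record files, then a
      batchable classification stage fanning out over them (one task per
      file), then reformatting; middle stage runs on the simulated queue,
      so this chain also mixes backends.
    * ``spectra-chain`` — a three-step chain alternating between the
      simulated queue and local execution (mixed-backend processing).
    """
    docs = {
        "genome-annotation": {
            "name": "genome-annotation",
            "user": user,
            "metadata": {"usecase": "1", "kind": "annotation"},
            "jobs": [
                {"tool": "upper", "args": {"infile": input_uri}},
                {"tool": "mask", "args": {"infile": {"from_job": 0}}},
                {"tool": "predict", "args": {"infile": {"from_job": 1}}},
                {"tool": "tognff", "args": {"infile": {"from_job": 2}}},
            ],
        },
        "orf-screen": {
            "name": "orf-screen",
            "user": user,
            "metadata": {"usecase": "2", "kind": "screen"},
            "jobs": [
                {"tool": "orfs", "args": {"infile": input_uri}},
                {"tool": "classify", "args": {"infile": {"from_job": 0}}},
                {
                    "tool": "tognff",
                    "args": {"infile": {"from_job": 1, "pattern": "*.hit.fa"}},
                },
            ],
        },
        "spectra-chain": {
            "name": "spectra-chain",
            "user": user,
            "metadata": {"usecase": "3", "kind": "proteomics"},
            "jobs": [
                {"tool": "sleepy", "args": {"infile": input_uri, "delay": "0.01"}},
                {"tool": "upper", "args": {"infile": {"from_job": 0}}},
                {"tool": "mask", "args": {"infile": {"from_job": 1}}},
            ],
        },
    }
    for doc in docs.values():
        WorkflowRequest.from_json(doc)  # structural sanity
    return docs
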