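"""Scriptable stand-in for the search executable.

Lets the executor and test suite exercise the full job lifecycle
without a real alignment binary: output is deterministic per input, and
failures (generic, repeated, out-of-memory) are scripted per batch via
a JSON behavior file.  Invoked the same way as a real search program::

    python -m batchblast.mock_blast -query batch_002.fa -db mydb \
        -num_threads 4 [--behavior spec.json --state-dir DIR] [ignored opts]

Behavior spec: a JSON object keyed by batch index (string) with an
optional ``"default"`` entry; each value may set ``fail_times`` (fail
with exit 1 on the first N invocations, then succeed), ``oom`` (always
exit with the reserved OOM code) or ``exit_code``.  ``--state-dir``
holds per-batch invocation counters so ``fail_times`` persists across
process invocations.

Output: one tab-separated line per query — id, batch index, CRC32 of
the sequence — so result completeness is checkable downstream.
"""

from __future__ import annotations

import argparse
import json
import re
import sys
import zlib
from pathlib import Path

from .orchestrator import OOM_EXIT_CODE
from .query_split import parse_fasta


def batch_index_from_name(path: str) -> int:
    m = re.search(r"batch_(\d+)", Path(path).name)
    return int(m.group(1)) if m else 0


def _bump_counter(state_dir: str, index: int) -> int:
    """Increment and return the invocation count for a batch (1-based)."""
    Path(state_dir).mkdir(parents=True, exist_ok=True)
    counter = Path(state_dir) / f"attempts_{index:03d}"
    n = int(counter.read_text()) + 1 if counter.exists() else 1
    counter.write_text(str(n))
    return n


def run(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(prog="mock_blast", add_help=False)
    parser.add_argument("-query", required=True)
    parser.add_argument("-db", default="mockdb")
    parser.add_argument("-num_threads", type=int, default=1)
    parser.add_argument("--behavior", default=None)
    parser.add_argument("--state-dir", default=None)
    args, _unknown = parser.parse_known_args(argv)   # opaque options ignored

    index = batch_index_from_name(args.query)
    behavior: dict = {}
    if args.behavior:
        spec = json.loads(Path(args.behavior).read_text())
        behavior = spec.get(str(index), spec.get("default", {}))

    if behavior.get("oom"):
        print(f"mock_blast: batch {index}: out of memory", file=sys.stderr)
        return OOM_EXIT_CODE
    fail_times = int(behavior.get("fail_times", 0))
    if fail_times:
        if not args.state_dir:
            print("mock_blast: fail_times requires --state-dir", file=sys.stderr)
            return 2
        attempt = _bump_counter(args.state_dir, index)
        if attempt <= fail_times:
            print(f"mock_blast: batch {index}: scripted failure "
                  f"{attempt}/{fail_times}", file=sys.stderr)
            return int(behavior.get("exit_code", 1))
    elif "exit_code" in behavior:
        return int(behavior["exit_code"])

    with open(args.query) as fh:
        for rec in parse_fasta(fh):
            checksum = zlib.crc32(rec.payload.encode())
            print(f"{rec.id}\t{index}\t{checksum:08x}")
    return 0


if __name__ == "__main__":
    sys.exit(run())
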