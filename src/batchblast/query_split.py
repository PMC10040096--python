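"""FASTA query reading and length-bounded batching.

Distributed search parallelises over groups of query sequences.  A batch
is closed as soon as its summed sequence length reaches the configured
batch length; an individual sequence is never split between batches, so
a sequence longer than the threshold forms its own oversized batch.
Batches are the unit of work handed to the search executable.
"""

from __future__ import annotations

import gzip
import io
import random
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .objectstore import ObjectStore

GZIP_MAGIC = b"\x1f\x8b"


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the 1-based line number."""


@dataclass(frozen=True)
class SequenceRecord:
    """One query sequence: definition-line id, length, and sequence text."""

    id: str
    payload: str

    @property
    def length(self) -> int:
        return len(self.payload)


@dataclass
class QueryBatch:
    """An ordered group of records whose lengths sum to ``total_length``."""

    index: int
    records: list[SequenceRecord] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)


@dataclass
class SplitPlan:
    """The full batching of an input: ordered batches plus input totals."""

    batches: list[QueryBatch]
    batch_len: int
    total_sequences: int
    total_length: int


def _open_maybe_gzip(raw: IO[bytes]) -> IO[str]:
    head = raw.read(2)
    raw.seek(0)
    if head == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(raw, "rb"))
    return io.TextIOWrapper(raw)


def parse_fasta(handle: IO[str]) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA text handle.

    Yields records in file order; sequence lengths exclude all
    whitespace.  Sequence data before the first header, or a header with
    no sequence, raises :class:`FastaParseError` with the line number.
    Memory use is bounded by the longest single record, not the file.
    """
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    lineno = 0
    for lineno, line in enumerate(handle, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header is not None:
                if not chunks:
                    raise FastaParseError(
                        f"line {header_line}: record {header!r} has no sequence")
                yield SequenceRecord(id=header, payload="".join(chunks))
            header = stripped[1:].split()[0] if len(stripped) > 1 else ""
            if not header:
                raise FastaParseError(f"line {lineno}: empty definition line")
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before first '>' header")
            chunks.append("".join(stripped.split()))
    if header is not None:
        if not chunks:
            raise FastaParseError(
                f"line {header_line}: record {header!r} has no sequence")
        yield SequenceRecord(id=header, payload="".join(chunks))


def read_sequences(source: str, store: ObjectStore | None = None
                   ) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA locator, transparently gunzipping.

    Gzip input is detected by its magic bytes, not the filename.  An
    empty file yields an empty stream (emptiness is policed by callers
    that need at least one query).
    """
    store = store or ObjectStore()
    with store.open_read(source) as raw:
        yield from parse_fasta(_open_maybe_gzip(raw))


def split_queries(records: Iterable[SequenceRecord], batch_len: int) -> SplitPlan:
    """Partition a record stream into length-bounded batches.

    Greedy close-on-reach rule: records are appended to the open batch,
    which closes as soon as its total length reaches ``batch_len`` (the
    closing record included).  Every batch except possibly the last is
    therefore at least ``batch_len`` long, and dropping its final record
    would take it below the threshold (minimal overshoot).  Input order
    is preserved and no record is ever split.
    """
    if batch_len < 1:
        raise ValueError(f"batch_len must be >= 1, got {batch_len}")
    batches: list[QueryBatch] = []
    current: list[SequenceRecord] = []
    current_len = 0
    n_seqs = 0
    total = 0
    for rec in records:
        current.append(rec)
        current_len += rec.length
        n_seqs += 1
        total += rec.length
        if current_len >= batch_len:
            batches.append(QueryBatch(index=len(batches), records=current))
            current = []
            current_len = 0
    if current:
        batches.append(QueryBatch(index=len(batches), records=current))
    return SplitPlan(batches=batches, batch_len=batch_len,
                     total_sequences=n_seqs, total_length=total)


def format_fasta(records: Iterable[SequenceRecord], width: int = 80) -> str:
    out: list[str] = []
    for rec in records:
        out.append(f">{rec.id}")
        seq = rec.payload
        out.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + ("\n" if out else "")


def batch_object_name(index: int) -> str:
    return f"batch_{index:03d}.fa"


def write_batches(plan: SplitPlan, dest: str,
                  store: ObjectStore | None = None) -> list[str]:
    """Write one uncompressed FASTA object per batch under ``dest``.

    Objects are named by zero-padded batch index (``batch_000.fa`` …) so
    listing the destination reproduces batch order.  Returns the object
    locators in batch order.
    """
    store = store or ObjectStore()
    locators = []
    for batch in plan.batches:
        loc = store.join(dest, batch_object_name(batch.index))
        store.write_text(loc, format_fasta(batch.records))
        locators.append(loc)
    return locators


_ALPHABET = "ACGT"


def generate_fixture_fasta(n_seqs: int, length_range: tuple[int, int],
                           seed: int, alphabet: str = _ALPHABET) -> str:
    """Deterministic random FASTA text for tests and demos.

    Sequence lengths are uniform on ``length_range`` (inclusive); ids are
    ``seq_0000`` … and unique.  The same seed always yields byte-identical
    output.
    """
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError(f"invalid length range {length_range}")
    rng = random.Random(seed)
    records = []
    for i in range(n_seqs):
        length = rng.randint(lo, hi)
        seq = "".join(rng.choice(alphabet) for _ in range(length))
        records.append(SequenceRecord(id=f"seq_{i:04d}", payload=seq))
    return format_fasta(records)
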