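"""BLAST database metadata and the memory a search needs.

Database metadata (generated alongside modern BLAST databases) records
both the total on-disk size of the database and the smaller
``bytes_to_cache``: the portion — sequence data plus search indices —
that must sit in main memory for the search to run efficiently.  The
planner provisions instances against ``bytes_to_cache`` (with a safety
margin), not against the full database size, because post-search report
generation touches only a fraction of the remaining files.
"""

from __future__ import annotations

import json
import math
import random
from decimal import Decimal
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .objectstore import ObjectStore

GIB = 2 ** 30


class Molecule(str, Enum):
    protein = "protein"
    nucleotide = "nucleotide"


class MetadataError(ValueError):
    """Missing or inconsistent database metadata."""


class DbMetadata(BaseModel):
    name: str
    molecule: Molecule
    num_letters: int = Field(ge=1)
    num_sequences: int = Field(ge=1)
    total_bytes: int = Field(gt=0)
    bytes_to_cache: int = Field(gt=0)
    version: str = "1.0"

    @model_validator(mode="after")
    def _consistent(self):
        if self.bytes_to_cache > self.total_bytes:
            raise ValueError(
                f"bytes_to_cache ({self.bytes_to_cache}) exceeds "
                f"total_bytes ({self.total_bytes})")
        if self.num_letters < self.num_sequences:
            raise ValueError("num_letters must be >= num_sequences")
        return self

    def render(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2) + "\n"


class MemoryRequirement(BaseModel):
    """Main memory the planner must provision: cached bytes x margin."""

    bytes_needed: int = Field(gt=0)
    margin: float = Field(ge=1.0)


def load_metadata(source: str, store: ObjectStore | None = None) -> DbMetadata:
    """Load and validate a JSON metadata document from a locator."""
    store = store or ObjectStore()
    try:
        doc = json.loads(store.read_text(source))
    except json.JSONDecodeError as exc:
        raise MetadataError(f"{source}: not valid JSON: {exc}") from exc
    required = {"name", "molecule", "num_letters", "num_sequences",
                "total_bytes", "bytes_to_cache"}
    missing = required - doc.keys()
    if missing:
        raise MetadataError(
            f"{source}: missing metadata field(s): {', '.join(sorted(missing))}")
    try:
        return DbMetadata(**doc)
    except ValueError as exc:
        raise MetadataError(f"{source}: {exc}") from exc


def memory_requirement(meta: DbMetadata, margin: float = 1.1) -> MemoryRequirement:
    """Memory to provision: ``ceil(bytes_to_cache * margin)``.

    The default 10% margin leaves headroom over the cached working set
    for the search processes themselves; it is surfaced in the plan
    report and configurable.
    """
    if margin < 1:
        raise ValueError(f"margin must be >= 1, got {margin}")
    # Decimal avoids float error pushing ceil one byte over an exact product
    needed = math.ceil(Decimal(str(margin)) * meta.bytes_to_cache)
    return MemoryRequirement(bytes_needed=needed, margin=margin)


def synth_metadata(num_letters: int, molecule: Molecule | str,
                   seed: int, name: str | None = None) -> DbMetadata:
    """Deterministic synthetic metadata with realistic size ratios.

    Protein databases store ~1 byte per residue of core searchable data,
    nucleotide databases ~0.25 byte per base (2-bit packing); indices add
    a seeded 10–40% on top, and non-cached files (titles, taxonomy)
    roughly double the on-disk total.
    """
    if num_letters < 1:
        raise ValueError("num_letters must be >= 1")
    molecule = Molecule(molecule)
    rng = random.Random(seed)
    per_letter = 1.0 if molecule is Molecule.protein else 0.25
    index_overhead = 1.0 + rng.uniform(0.1, 0.4)
    bytes_to_cache = max(1, math.ceil(num_letters * per_letter * index_overhead))
    total_bytes = math.ceil(bytes_to_cache * (1.0 + rng.uniform(0.3, 1.0)))
    mean_len = 350 if molecule is Molecule.protein else 2000
    num_sequences = max(1, min(num_letters, round(num_letters / mean_len)))
    return DbMetadata(
        name=name or f"synthdb_{molecule.value}_{seed}",
        molecule=molecule,
        num_letters=num_letters,
        num_sequences=num_sequences,
        total_bytes=total_bytes,
        bytes_to_cache=bytes_to_cache,
    )
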