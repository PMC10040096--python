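"""Resource planning: instance type, thread layout, batch length.

The instance type bounds the CPUs and RAM available to the search, so
the planner picks the *smallest* catalog instance whose RAM covers the
database's in-memory working set (plus margin).  Thread layout follows
the rule that a search process should use at most 16 threads — larger
instances run several processes side by side.  Batch length defaults
target a per-job runtime of roughly 5–30 minutes and can always be
overridden in the run configuration.
"""

from __future__ import annotations

import csv
import io
import json
import math
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .config import Program, Provider, RunConfig
from .db_metadata import GIB, DbMetadata, MemoryRequirement, memory_requirement
from .objectstore import ObjectStore


class PlannerError(ValueError):
    """No feasible plan for the given catalog/requirement."""


class InstanceType(BaseModel):
    name: str
    provider: Provider
    vcpus: int = Field(ge=1)
    ram_bytes: int = Field(gt=0)
    hourly_price: float = Field(gt=0)
    spot_discount: float = Field(gt=0, le=1)
    local_ssd_bytes: int = Field(ge=0, default=0)


class ThreadMode(str, Enum):
    db_partition = "db_partition"   # threads cooperate on one database scan
    query_batch = "query_batch"     # small databases: per-query threading


class ThreadPlan(BaseModel):
    processes: int = Field(ge=1)
    threads_per_process: int = Field(ge=1, le=16)
    mode: ThreadMode


class SearchPlan(BaseModel):
    instance: InstanceType
    thread_plan: ThreadPlan
    batch_len: int = Field(ge=1)
    max_nodes: int = Field(ge=1)
    preemptible: bool
    memory: MemoryRequirement


MAX_THREADS_PER_PROCESS = 16

#: databases whose cached bytes fall below this use per-query threading
SMALL_DB_THRESHOLD_BYTES = 4 * GIB

#: db-size class boundary above which batches are halved (slower per-base search)
LARGE_DB_THRESHOLD_BYTES = 50 * GIB

#: base batch lengths (bases/residues) per program family, calibrated to
#: put a single job in the minutes-not-hours range on a 16-vCPU share
BASE_BATCH_LEN = {
    Program.blastn: 5_000_000,
    Program.megablast: 5_000_000,
    Program.blastp: 20_000,
    Program.blastx: 20_000,
    Program.tblastn: 20_000,
    Program.tblastx: 20_000,
}


def _entry_from_mapping(row: dict) -> InstanceType:
    ram = row.get("ram_bytes")
    if ram is None and "ram_gib" in row:
        ram = round(float(row["ram_gib"]) * GIB)
    ssd = row.get("local_ssd_bytes")
    if ssd is None:
        ssd = round(float(row.get("local_ssd_gib", 0)) * GIB)
    return InstanceType(
        name=row["name"], provider=row["provider"],
        vcpus=int(row["vcpus"]), ram_bytes=int(ram),
        hourly_price=float(row["hourly_price"]),
        spot_discount=float(row["spot_discount"]),
        local_ssd_bytes=int(ssd),
    )


def parse_catalog(text: str) -> list[InstanceType]:
    """Parse a catalog from JSON (list of objects) or CSV text.

    RAM/disk may be given as ``ram_bytes``/``local_ssd_bytes`` or the
    friendlier ``ram_gib``/``local_ssd_gib``.  Duplicate names are
    rejected; pydantic enforces positive prices and valid discounts.
    """
    stripped = text.lstrip()
    if stripped.startswith("["):
        rows = json.loads(text)
    else:
        rows = list(csv.DictReader(io.StringIO(text)))
    entries = [_entry_from_mapping(row) for row in rows]
    names = [e.name for e in entries]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise PlannerError(f"duplicate instance name(s): {', '.join(sorted(dupes))}")
    return entries


def load_catalog(source: str | None = None,
                 store: ObjectStore | None = None) -> list[InstanceType]:
    """Load an instance catalog; ``None`` loads the bundled fixture."""
    if source is None:
        text = (resources.files("batchblast") / "data" / "catalog.json").read_text()
    else:
        text = (store or ObjectStore()).read_text(source)
    return parse_catalog(text)


def select_instance(requirement: MemoryRequirement,
                    catalog: Sequence[InstanceType],
                    provider: Provider | None = None) -> InstanceType:
    """Smallest-sufficient selection.

    Returns the instance with minimal RAM among those with
    ``ram_bytes >= bytes_needed`` (after the optional provider filter);
    ties break on lower hourly price, then lexicographic name.
    """
    pool = [e for e in catalog if provider is None or e.provider == provider]
    if not pool:
        raise PlannerError("instance catalog is empty after provider filter")
    sufficient = [e for e in pool if e.ram_bytes >= requirement.bytes_needed]
    if not sufficient:
        biggest = max(e.ram_bytes for e in pool)
        raise PlannerError(
            f"no catalog instance has enough memory: need "
            f"{requirement.bytes_needed / GIB:.1f} GiB, largest available is "
            f"{biggest / GIB:.1f} GiB (request a larger machine type explicitly)")
    return min(sufficient, key=lambda e: (e.ram_bytes, e.hourly_price, e.name))


def thread_plan(instance: InstanceType, meta: DbMetadata,
                small_db_threshold: int = SMALL_DB_THRESHOLD_BYTES) -> ThreadPlan:
    """Process/thread layout for an instance.

    At most 16 threads per search process; instances with more vCPUs run
    ``floor(vcpus / 16)`` processes concurrently.  Databases whose
    cached bytes fall under ``small_db_threshold`` use the per-query
    threading model, which is more efficient when the database scan is
    cheap.
    """
    processes = max(1, instance.vcpus // MAX_THREADS_PER_PROCESS)
    threads = min(instance.vcpus, MAX_THREADS_PER_PROCESS)
    mode = (ThreadMode.query_batch if meta.bytes_to_cache < small_db_threshold
            else ThreadMode.db_partition)
    return ThreadPlan(processes=processes, threads_per_process=threads, mode=mode)


def default_batch_len(program: Program, meta: DbMetadata,
                      query_total_length: int | None = None) -> int:
    """Default bases/residues per batch for a (program, db, query) shape.

    Starts from the per-program base, halves it for large databases
    (each base searched is slower) and doubles it for small ones; very
    large query sets (>= 100x the base) double the batch to cap the job
    count.  Purely a default — an explicit ``batch-len`` always wins.
    """
    program = Program(program)
    base = BASE_BATCH_LEN[program]
    if meta.bytes_to_cache >= LARGE_DB_THRESHOLD_BYTES:
        length = base // 2
    elif meta.bytes_to_cache < SMALL_DB_THRESHOLD_BYTES:
        length = base * 2
    else:
        length = base
    if query_total_length is not None and query_total_length >= 100 * base:
        length *= 2
    return max(1, length)


def make_plan(config: RunConfig, meta: DbMetadata,
              catalog: Sequence[InstanceType],
              query_total_length: int | None = None,
              margin: float = 1.1) -> SearchPlan:
    """Assemble the full search plan from configuration and metadata.

    A ``machine-type`` override in the configuration is honored even if
    oversized, but an override *smaller* than the memory requirement is
    rejected — the search would thrash or die.
    """
    req = memory_requirement(meta, margin=margin)
    if config.machine_type:
        matches = [e for e in catalog
                   if e.name == config.machine_type and e.provider == config.provider]
        if not matches:
            raise PlannerError(
                f"machine-type override {config.machine_type!r} not in catalog "
                f"for provider {config.provider.value}")
        instance = matches[0]
        if instance.ram_bytes < req.bytes_needed:
            raise PlannerError(
                f"machine-type override {instance.name} has "
                f"{instance.ram_bytes / GIB:.1f} GiB RAM but the search needs "
                f"{req.bytes_needed / GIB:.1f} GiB")
    else:
        instance = select_instance(req, catalog, provider=config.provider)
    batch_len = config.batch_len or default_batch_len(
        config.program, meta, query_total_length)
    return SearchPlan(
        instance=instance,
        thread_plan=thread_plan(instance, meta),
        batch_len=batch_len,
        max_nodes=config.num_nodes,
        preemptible=config.use_preemptible,
        memory=req,
    )
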