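"""Run lifecycle: submit, execute, status, delete.

``submit`` validates the configuration, splits the queries, computes
the search plan and persists everything in a single JSON *manifest*
under the results locator, with all jobs pending.  ``execute_run``
drives the pending jobs through the local executor, checkpointing the
manifest after every job transition so ``status`` and ``delete`` can
run from another process.  ``delete`` releases batch objects and worker
state but always leaves already-written result objects in place, and is
idempotent.
"""

from __future__ import annotations

import json
import sys
import uuid
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import RunConfig
from .db_metadata import DbMetadata, MetadataError, load_metadata
from .objectstore import ObjectStore
from .orchestrator import (FailureKind, Job, JobState, RunResult, make_jobs,
                           run_local)
from .planner import InstanceType, SearchPlan, load_catalog, make_plan
from .query_split import read_sequences, split_queries, write_batches

MANIFEST_NAME = "manifest.json"
BATCH_PREFIX = "query_batches"

#: default invocation template: the bundled mock executable
MOCK_COMMAND = (f"{sys.executable} -m batchblast.mock_blast "
                "-query {batch} -db {db} -num_threads {threads} {options}")


class RunError(RuntimeError):
    pass


class RunNotFound(RunError):
    pass


@dataclass(frozen=True)
class RunHandle:
    run_id: str
    config: RunConfig
    state_dir: str      # locator prefix holding the manifest

    @property
    def manifest_locator(self) -> str:
        return ObjectStore().join(self.state_dir, MANIFEST_NAME)


@dataclass(frozen=True)
class StatusReport:
    counts: dict[str, int]      # per job state
    phase: str                  # initializing|running|succeeded|failed|deleted

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class TeardownReport:
    run_id: str
    noop: bool
    results_retained: int


def _jobs_to_doc(jobs: Sequence[Job]) -> list[dict]:
    return [{
        "job_id": j.job_id, "batch_index": j.batch_index,
        "state": j.state.value, "attempts": j.attempts,
        "last_failure": j.last_failure.value,
        "result_locator": j.result_locator,
    } for j in jobs]


def _jobs_from_doc(doc: list[dict]) -> list[Job]:
    return [Job(job_id=d["job_id"], batch_index=d["batch_index"],
                state=JobState(d["state"]), attempts=d["attempts"],
                last_failure=FailureKind(d["last_failure"]),
                result_locator=d.get("result_locator")) for d in doc]


def _write_manifest(store: ObjectStore, locator: str, doc: dict) -> None:
    store.write_text(locator, json.dumps(doc, indent=2) + "\n")


def _read_manifest(store: ObjectStore, results: str) -> dict:
    locator = store.join(results, MANIFEST_NAME)
    if not store.exists(locator):
        raise RunNotFound(f"no run manifest at {locator}")
    return json.loads(store.read_text(locator))


def resolve_db_metadata(db: str, store: ObjectStore) -> DbMetadata:
    """Locate metadata for a database identifier.

    Accepts a direct locator to the JSON document, or a database name
    with the metadata stored alongside as ``<name>.json``.
    """
    for candidate in (db, db + ".json"):
        if store.exists(candidate):
            return load_metadata(candidate, store)
    raise MetadataError(f"no database metadata found for {db!r} "
                        f"(looked for {db} and {db}.json)")


def submit(config: RunConfig, store: ObjectStore | None = None,
           catalog: Sequence[InstanceType] | None = None,
           margin: float = 1.1) -> RunHandle:
    """Split queries, plan resources, enqueue jobs, persist the manifest.

    Jobs are enqueued pending; execution is a separate step
    (:func:`execute_run`).  Fails before allocating anything when the
    query file is empty or unreadable, and refuses to overwrite the
    manifest of an active (non-deleted, non-terminal) run.
    """
    store = store or ObjectStore()
    manifest_loc = store.join(config.results, MANIFEST_NAME)
    if store.exists(manifest_loc):
        existing = json.loads(store.read_text(manifest_loc))
        if existing.get("phase") not in ("deleted", "succeeded", "failed"):
            raise RunError(
                f"an active run ({existing.get('run_id')}) already uses "
                f"results locator {config.results}; delete it first")

    records = list(read_sequences(config.queries, store))
    if not records:
        raise RunError(f"query file {config.queries} contains no sequences")
    total_length = sum(r.length for r in records)

    meta = resolve_db_metadata(config.db, store)
    catalog = catalog if catalog is not None else load_catalog()
    plan = make_plan(config, meta, catalog,
                     query_total_length=total_length, margin=margin)

    split = split_queries(records, plan.batch_len)
    batch_dest = store.join(config.results, BATCH_PREFIX)
    batch_locators = write_batches(split, batch_dest, store)
    jobs = make_jobs(len(split.batches))

    run_id = uuid.uuid4().hex[:12]
    doc = {
        "run_id": run_id,
        "phase": "submitted",
        "config": json.loads(config.model_dump_json()),
        "plan": json.loads(plan.model_dump_json()),
        "db_metadata": json.loads(meta.model_dump_json()),
        "totals": {"sequences": split.total_sequences,
                   "length": split.total_length},
        "batch_locators": batch_locators,
        "jobs": _jobs_to_doc(jobs),
        "deleted": False,
    }
    _write_manifest(store, manifest_loc, doc)
    return RunHandle(run_id=run_id, config=config, state_dir=config.results)


def load_handle(config: RunConfig, store: ObjectStore | None = None) -> RunHandle:
    store = store or ObjectStore()
    doc = _read_manifest(store, config.results)
    return RunHandle(run_id=doc["run_id"], config=config,
                     state_dir=config.results)


def status(handle: RunHandle, store: ObjectStore | None = None) -> StatusReport:
    """Read-only snapshot of persisted job states."""
    store = store or ObjectStore()
    doc = _read_manifest(store, handle.state_dir)
    jobs = _jobs_from_doc(doc["jobs"])
    counts = {s.value.lower(): 0 for s in JobState}
    for j in jobs:
        counts[j.state.value.lower()] += 1
    if doc.get("deleted"):
        phase = "deleted"
    elif not jobs:
        phase = "initializing"
    elif counts["failed"] > 0:
        phase = "failed"
    elif counts["succeeded"] == len(jobs):
        phase = "succeeded"
    elif counts["running"] > 0 or doc["phase"] == "running":
        phase = "running"
    else:
        phase = "initializing" if doc["phase"] == "submitted" else doc["phase"]
    return StatusReport(counts=counts, phase=phase)


def execute_run(handle: RunHandle, command_template: str = MOCK_COMMAND,
                workers: int = 1,
                store: ObjectStore | None = None) -> RunResult:
    """Run every pending job locally, checkpointing the manifest."""
    store = store or ObjectStore()
    doc = _read_manifest(store, handle.state_dir)
    if doc.get("deleted"):
        raise RunError(f"run {doc['run_id']} has been deleted")
    jobs = _jobs_from_doc(doc["jobs"])
    plan = SearchPlan(**doc["plan"])
    manifest_loc = store.join(handle.state_dir, MANIFEST_NAME)
    doc["phase"] = "running"
    _write_manifest(store, manifest_loc, doc)

    def checkpoint(job: Job) -> None:
        for i, d in enumerate(doc["jobs"]):
            if d["job_id"] == job.job_id:
                doc["jobs"][i] = _jobs_to_doc([job])[0]
        _write_manifest(store, manifest_loc, doc)

    result = run_local(
        jobs, plan, command_template, doc["batch_locators"],
        handle.state_dir, db=handle.config.db,
        options=handle.config.options, workers=workers, store=store,
        on_update=checkpoint)
    doc["jobs"] = _jobs_to_doc(result.jobs)
    doc["phase"] = result.phase
    _write_manifest(store, manifest_loc, doc)
    return result


def delete(handle: RunHandle, store: ObjectStore | None = None) -> TeardownReport:
    """Release run resources; results already written stay readable.

    Removes the query-batch objects and marks the manifest deleted.
    A second call is a no-op success.
    """
    store = store or ObjectStore()
    doc = _read_manifest(store, handle.state_dir)
    retained = sum(1 for d in doc["jobs"] if d.get("result_locator")
                   and store.exists(d["result_locator"]))
    if doc.get("deleted"):
        return TeardownReport(run_id=doc["run_id"], noop=True,
                              results_retained=retained)
    store.delete_prefix(store.join(handle.state_dir, BATCH_PREFIX))
    doc["deleted"] = True
    doc["batch_locators"] = []
    doc["instances"] = []
    _write_manifest(store, store.join(handle.state_dir, MANIFEST_NAME), doc)
    return TeardownReport(run_id=doc["run_id"], noop=False,
                          results_retained=retained)
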