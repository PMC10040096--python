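"""Job state machine, local executor and shutdown monitor.

Each query batch becomes one job.  Jobs that fail for a generic reason
(non-zero exit, instance preemption) are retried up to three times after
the initial attempt; a job that runs out of memory is flagged failed
immediately, because retrying on the same instance type cannot succeed.
A periodic monitor tears the run down once every job has succeeded or
any job has failed — results of already-completed jobs survive.
"""

from __future__ import annotations

import gzip
import os
import shlex
import shutil
import subprocess
from collections import deque
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence

from .objectstore import ObjectStore
from .planner import SearchPlan

#: exit code the executor reserves for out-of-memory (128 + SIGKILL, the
#: code an OOM-killed process actually reports)
OOM_EXIT_CODE = 137

#: executions allowed per job: 1 initial attempt + 3 retries
MAX_ATTEMPTS = 4


class JobState(str, Enum):
    PENDING = "PENDING"
    RUNNING = "RUNNING"
    SUCCEEDED = "SUCCEEDED"
    FAILED = "FAILED"


class FailureKind(str, Enum):
    none = "none"
    generic = "generic"
    oom = "oom"
    preempted = "preempted"


class JobEvent(str, Enum):
    start = "start"
    success = "success"
    failure_generic = "failure_generic"
    failure_oom = "failure_oom"
    preempted = "preempted"


class StateMachineError(RuntimeError):
    """An event was applied to a job in a state where it is illegal."""


@dataclass(frozen=True)
class Job:
    """Per-batch execution record."""

    job_id: str
    batch_index: int
    state: JobState = JobState.PENDING
    attempts: int = 0
    last_failure: FailureKind = FailureKind.none
    result_locator: Optional[str] = None

    def __post_init__(self):
        if self.attempts > MAX_ATTEMPTS:
            raise ValueError(f"attempts may not exceed {MAX_ATTEMPTS}")

    @property
    def terminal(self) -> bool:
        return self.state in (JobState.SUCCEEDED, JobState.FAILED)


def make_jobs(n_batches: int) -> list[Job]:
    return [Job(job_id=f"job-{i:03d}", batch_index=i) for i in range(n_batches)]


def next_state(job: Job, event: JobEvent, result_locator: str | None = None) -> Job:
    """Apply one lifecycle event; returns a new Job, never mutates.

    ``start`` is legal only from PENDING (and counts an execution);
    every other event is legal only from RUNNING.  Generic failures and
    preemptions requeue the job while retry budget remains; out-of-memory
    fails immediately with no retry.
    """
    event = JobEvent(event)
    if event is JobEvent.start:
        if job.state is not JobState.PENDING:
            raise StateMachineError(
                f"{job.job_id}: cannot start from {job.state.value}")
        return replace(job, state=JobState.RUNNING, attempts=job.attempts + 1)
    if job.state is not JobState.RUNNING:
        raise StateMachineError(
            f"{job.job_id}: event {event.value} illegal from {job.state.value}")
    if event is JobEvent.success:
        return replace(job, state=JobState.SUCCEEDED,
                       last_failure=FailureKind.none,
                       result_locator=result_locator)
    if event is JobEvent.failure_oom:
        return replace(job, state=JobState.FAILED, last_failure=FailureKind.oom)
    kind = (FailureKind.preempted if event is JobEvent.preempted
            else FailureKind.generic)
    if job.attempts <= MAX_ATTEMPTS - 1:
        return replace(job, state=JobState.PENDING, last_failure=kind)
    return replace(job, state=JobState.FAILED, last_failure=kind)


class MonitorAction(str, Enum):
    none = "none"
    teardown = "teardown"


def monitor_step(jobs: Sequence[Job], cluster=None) -> MonitorAction:
    """One tick of the auto-shutdown monitor (default cadence: 5 min).

    Tear everything down once every job has succeeded or any job has
    failed; idempotent — repeated teardown decisions are harmless.
    """
    if not jobs:
        return MonitorAction.none
    if any(j.state is JobState.FAILED for j in jobs):
        return MonitorAction.teardown
    if all(j.state is JobState.SUCCEEDED for j in jobs):
        return MonitorAction.teardown
    return MonitorAction.none


@dataclass
class RunResult:
    jobs: list[Job]
    phase: str                      # "succeeded" or "failed"
    result_locators: list[str] = field(default_factory=list)


def result_object_name(batch_index: int) -> str:
    return f"batch_{batch_index:03d}.out.gz"


def _resolve_executable(command_template: str) -> None:
    argv0 = shlex.split(command_template)[0]
    if os.path.sep in argv0:
        if not os.path.exists(argv0):
            raise FileNotFoundError(f"search executable not found: {argv0}")
    elif shutil.which(argv0) is None:
        raise FileNotFoundError(f"search executable not found on PATH: {argv0}")


def run_local(jobs: Sequence[Job], plan: SearchPlan, command_template: str,
              batch_locators: Sequence[str], results: str, *, db: str,
              options: str = "", workers: int = 1,
              store: ObjectStore | None = None,
              oom_exit_code: int = OOM_EXIT_CODE,
              on_update: Callable[[Job], None] | None = None) -> RunResult:
    """Drive every job to a terminal state with local worker processes.

    ``command_template`` is the search invocation with substitution
    slots ``{batch}`` (batch FASTA path), ``{db}``, ``{threads}`` and
    ``{options}`` (the opaque option string, passed through verbatim).
    Successful output is gzip-compressed and written to
    ``<results>/batch_<index>.out.gz``.  Exit code ``oom_exit_code``
    maps to an out-of-memory failure (fail-fast); any other non-zero
    exit is a generic, retryable failure.  Retries requeue behind
    outstanding work; once any job has failed, no new work is started
    but in-flight jobs finish and keep their results.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    _resolve_executable(command_template)
    store = store or ObjectStore()

    jobs = list(jobs)
    by_id = {j.job_id: i for i, j in enumerate(jobs)}
    queue: deque[str] = deque(j.job_id for j in jobs if not j.terminal)

    def update(job: Job) -> None:
        jobs[by_id[job.job_id]] = job
        if on_update:
            on_update(job)

    def execute(job: Job) -> tuple[str, int, bytes]:
        batch_path = store.resolve(batch_locators[job.batch_index])
        cmd = command_template.format(
            batch=batch_path, db=db,
            threads=plan.thread_plan.threads_per_process, options=options)
        proc = subprocess.run(shlex.split(cmd), capture_output=True)
        return job.job_id, proc.returncode, proc.stdout

    failed_seen = False
    with ThreadPoolExecutor(max_workers=workers) as pool:
        in_flight = {}
        while queue or in_flight:
            while queue and not failed_seen and len(in_flight) < workers:
                job_id = queue.popleft()
                job = next_state(jobs[by_id[job_id]], JobEvent.start)
                update(job)
                in_flight[pool.submit(execute, job)] = job_id
            if not in_flight:
                break
            done, _ = wait(in_flight, return_when=FIRST_COMPLETED)
            for fut in done:
                job_id = in_flight.pop(fut)
                job_id2, code, stdout = fut.result()
                job = jobs[by_id[job_id]]
                if code == 0:
                    loc = store.join(results, result_object_name(job.batch_index))
                    store.write_bytes(loc, gzip.compress(stdout))
                    update(next_state(job, JobEvent.success, result_locator=loc))
                elif code == oom_exit_code:
                    update(next_state(job, JobEvent.failure_oom))
                else:
                    job = next_state(job, JobEvent.failure_generic)
                    update(job)
                    if job.state is JobState.PENDING:
                        queue.append(job.job_id)
                if jobs[by_id[job_id]].state is JobState.FAILED:
                    failed_seen = True

    phase = "failed" if any(j.state is JobState.FAILED for j in jobs) else "succeeded"
    locators = [j.result_locator for j in jobs if j.result_locator]
    return RunResult(jobs=jobs, phase=phase, result_locators=locators)
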