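"""Discrete-event simulation of the batch cluster.

Replays the orchestration semantics — horizontal scaling up to the
configured node ceiling, per-instance startup delay, spot preemption as
a Poisson process, retry/fail-fast job transitions, idle scale-down lag
and the periodic shutdown monitor — against a virtual clock, so
makespan and billed instance-hours can be studied without a cloud
account.  Time is seconds internally; reports are in hours.

The event loop is a plain heap of (time, sequence, action) entries with
a seeded RNG, so every run is reproducible for a fixed seed.
"""

from __future__ import annotations

import csv
import heapq
import io
import itertools
import json
import math
import random
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .orchestrator import (Job, JobEvent, JobState, MonitorAction, monitor_step,
                           next_state)
from .planner import SearchPlan


@dataclass
class SimParams:
    """Simulation knobs.

    startup_delay_min
        Minutes between requesting an instance and it becoming
        productive (cluster configuration plus database installation).
    job_duration
        Either seconds per job (float) or a callable mapping batch
        length to seconds; a distributional model can close over the
        seeded RNG it needs.
    preemption_rate_per_hour
        Expected preemptions per instance-hour (0 for on-demand).
    monitor_interval_s
        Cadence of the auto-shutdown monitor (default 300 s = 5 min).
    scale_down_lag_min
        Minutes between an instance going idle and the scaler noticing
        and shutting it down.
    """

    startup_delay_min: float = 0.0
    job_duration: float | Callable[[int], float] = 3600.0
    preemption_rate_per_hour: float = 0.0
    monitor_interval_s: float = 300.0
    scale_down_lag_min: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.startup_delay_min < 0 or self.preemption_rate_per_hour < 0 \
                or self.scale_down_lag_min < 0:
            raise ValueError("rates and delays must be >= 0")
        if self.monitor_interval_s <= 0:
            raise ValueError("monitor_interval_s must be > 0")

    def duration_of(self, batch_len: int) -> float:
        if callable(self.job_duration):
            return float(self.job_duration(batch_len))
        return float(self.job_duration)


@dataclass
class _Instance:
    instance_id: int
    boot_time: float
    ready_time: float
    pricing_class: str
    busy: dict[str, float] = field(default_factory=dict)  # job_id -> end time
    idle_since: Optional[float] = None
    alive: bool = True
    shutdown_time: Optional[float] = None


@dataclass
class SimResult:
    """Outcome of one simulated run."""

    jobs: list[Job]
    makespan_hours: float
    billed_hours: dict[str, float]      # pricing class -> instance-hours
    instance_uptimes: list[dict]        # per-instance boot/shutdown records
    timeline: list[dict]                # chronological event log
    max_concurrent_instances: int
    n_preemptions: int

    @property
    def total_billed_hours(self) -> float:
        return sum(self.billed_hours.values())

    def timeline_json(self) -> str:
        return json.dumps(self.timeline, indent=2)

    def uptimes_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=[
            "instance_id", "pricing_class", "boot_time_s", "shutdown_time_s",
            "uptime_hours"])
        writer.writeheader()
        writer.writerows(self.instance_uptimes)
        return buf.getvalue()


def simulate(jobs: Sequence[Job], plan: SearchPlan, params: SimParams) -> SimResult:
    """Run the cluster simulation until every job is terminal.

    Scaling targets ``ceil(outstanding / slots)`` instances, capped at
    the plan's node ceiling; each instance offers ``processes`` slots
    from the thread plan.  Preemption kills an instance and requeues its
    running jobs through the ordinary retry budget.  Billed hours accrue
    from boot to shutdown per pricing class.  Deterministic per seed.
    """
    rng = random.Random(params.seed)
    jobs = list(jobs)
    index_of = {j.job_id: i for i, j in enumerate(jobs)}
    pending: list[str] = [j.job_id for j in jobs if j.state is JobState.PENDING]
    slots = plan.thread_plan.processes
    pricing_class = "preemptible" if plan.preemptible else "on-demand"

    heap: list[tuple[float, int, str, dict]] = []
    seq = itertools.count()
    timeline: list[dict] = []

    def push(t: float, kind: str, **payload):
        heapq.heappush(heap, (t, next(seq), kind, payload))

    def log(t: float, kind: str, **detail):
        timeline.append({"t_s": round(t, 3), "event": kind, **detail})

    instances: dict[int, _Instance] = {}
    inst_ids = itertools.count(1)
    max_concurrent = 0
    n_preempt = 0
    last_terminal_time = 0.0
    startup_s = params.startup_delay_min * 60.0
    lag_s = params.scale_down_lag_min * 60.0

    def alive_instances() -> list[_Instance]:
        return [i for i in instances.values() if i.alive]

    def schedule_preemption(inst: _Instance, now: float):
        if params.preemption_rate_per_hour <= 0:
            return
        dt_h = rng.expovariate(params.preemption_rate_per_hour)
        push(now + dt_h * 3600.0, "preempt", instance_id=inst.instance_id)

    def shutdown(inst: _Instance, now: float, reason: str):
        if not inst.alive:
            return
        inst.alive = False
        inst.shutdown_time = now
        log(now, "instance_shutdown", instance_id=inst.instance_id, reason=reason)

    def scale(now: float):
        nonlocal max_concurrent
        outstanding = len(pending) + sum(len(i.busy) for i in alive_instances())
        desired = min(plan.max_nodes, max(0, math.ceil(outstanding / slots)))
        while len(alive_instances()) < desired:
            inst = _Instance(instance_id=next(inst_ids), boot_time=now,
                             ready_time=now + startup_s,
                             pricing_class=pricing_class)
            instances[inst.instance_id] = inst
            push(inst.ready_time, "instance_ready", instance_id=inst.instance_id)
            log(now, "instance_requested", instance_id=inst.instance_id)
            schedule_preemption(inst, now)
        max_concurrent = max(max_concurrent, len(alive_instances()))

    def assign(now: float):
        for inst in alive_instances():
            if inst.ready_time > now:
                continue
            while pending and len(inst.busy) < slots:
                job_id = pending.pop(0)
                job = next_state(jobs[index_of[job_id]], JobEvent.start)
                jobs[index_of[job_id]] = job
                end = now + params.duration_of(plan.batch_len)
                inst.busy[job_id] = end
                inst.idle_since = None
                push(end, "job_done", instance_id=inst.instance_id, job_id=job_id)
                log(now, "job_started", job_id=job_id,
                    instance_id=inst.instance_id, attempt=job.attempts)

    def mark_idle(inst: _Instance, now: float):
        if inst.busy or not inst.alive:
            return
        inst.idle_since = now
        if lag_s == 0 and not pending:
            shutdown(inst, now, "idle")
        else:
            push(now + lag_s, "idle_check", instance_id=inst.instance_id,
                 since=now)

    def settle(job_id: str, event: JobEvent, now: float):
        nonlocal last_terminal_time
        job = next_state(jobs[index_of[job_id]], event,
                         result_locator=f"sim://{job_id}" if
                         event is JobEvent.success else None)
        jobs[index_of[job_id]] = job
        if job.state is JobState.PENDING:
            pending.append(job_id)
        elif job.terminal:
            last_terminal_time = max(last_terminal_time, now)

    push(params.monitor_interval_s, "monitor")
    scale(0.0)

    torn_down = False
    now = 0.0
    while heap:
        now, _, kind, payload = heapq.heappop(heap)
        if torn_down:
            break
        if kind == "instance_ready":
            inst = instances[payload["instance_id"]]
            if inst.alive:
                log(now, "instance_ready", instance_id=inst.instance_id)
                assign(now)
                mark_idle(inst, now)
        elif kind == "job_done":
            inst = instances[payload["instance_id"]]
            job_id = payload["job_id"]
            if not inst.alive or inst.busy.get(job_id) != now:
                continue    # stale event: instance preempted, job reassigned
            del inst.busy[job_id]
            settle(job_id, JobEvent.success, now)
            log(now, "job_succeeded", job_id=job_id,
                instance_id=inst.instance_id)
            assign(now)
            mark_idle(inst, now)
        elif kind == "preempt":
            inst = instances.get(payload["instance_id"])
            if inst is None or not inst.alive:
                continue
            n_preempt += 1
            victims = list(inst.busy)
            inst.busy.clear()
            shutdown(inst, now, "preempted")
            for job_id in victims:
                settle(job_id, JobEvent.preempted, now)
                log(now, "job_preempted", job_id=job_id,
                    instance_id=inst.instance_id)
            scale(now)
            assign(now)
        elif kind == "idle_check":
            inst = instances[payload["instance_id"]]
            if inst.alive and not inst.busy and \
                    inst.idle_since is not None and \
                    inst.idle_since <= payload["since"]:
                shutdown(inst, now, "idle")
        elif kind == "monitor":
            if monitor_step(jobs) is MonitorAction.teardown:
                for inst in alive_instances():
                    shutdown(inst, now, "teardown")
                log(now, "teardown")
                torn_down = True
            else:
                push(now + params.monitor_interval_s, "monitor")
        if all(j.terminal for j in jobs) and not alive_instances():
            break
        scale(now)
        assign(now)

    # close the books on anything still up (e.g. teardown raced the heap)
    for inst in instances.values():
        if inst.alive:
            shutdown(inst, now, "end")

    billed: dict[str, float] = {}
    uptimes = []
    for inst in instances.values():
        hours = (inst.shutdown_time - inst.boot_time) / 3600.0
        billed[inst.pricing_class] = billed.get(inst.pricing_class, 0.0) + hours
        uptimes.append({
            "instance_id": inst.instance_id,
            "pricing_class": inst.pricing_class,
            "boot_time_s": round(inst.boot_time, 3),
            "shutdown_time_s": round(inst.shutdown_time, 3),
            "uptime_hours": round(hours, 6),
        })
    return SimResult(
        jobs=jobs,
        makespan_hours=round(last_terminal_time / 3600.0, 6),
        billed_hours={k: round(v, 6) for k, v in billed.items()},
        instance_uptimes=uptimes,
        timeline=timeline,
        max_concurrent_instances=max_concurrent,
        n_preemptions=n_preempt,
    )
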