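# Methods

## The orchestration model

A run is defined by a three-section configuration (provider/region,
cluster shape, search). Submission splits the query set into batches,
computes a *search plan* (instance type, thread layout, batch length)
from database metadata and an instance catalog, writes one FASTA object
per batch, and persists a JSON manifest with one pending job per batch.
Execution, monitoring and teardown all operate on that manifest, which
is rewritten atomically (write-temp-then-rename) so `status` and
`delete` can run concurrently from another process.

Cloud storage is abstracted as an object store: `gs://` and `s3://`
locators map to paths under a configurable local root. This keeps
bucket semantics (objects, prefixes, idempotent deletes) without any
provider API; no real cloud integration is attempted or planned.

## Query batching

The splitter is a one-pass greedy rule: append records to the open
batch and close it as soon as its summed length reaches `batch-len`,
including the closing record. Consequences, all property-tested:

- every non-final batch `B` satisfies
  `batch_len ≤ len(B) < batch_len + len(last record of B)` (minimal
  overshoot);
- a record longer than `batch-len` forms its own oversized batch
  (records are never split);
- order and total length are conserved, and increasing `batch-len`
  never increases the batch count.

The boundary rule itself is a design choice — any rule that never
splits a record and bounds overshoot by one record would serve; this
one admits a streaming implementation with O(1) state.

## Memory requirement and instance selection

Database metadata carries `bytes_to_cache`, the sequence-plus-index
working set that must be resident for the search to run at disk-free
speed; it is smaller than the database's total file size because report
generation touches only a fraction of the remaining files (titles,
taxonomy). The planner provisions

    bytes_needed = ceil(bytes_to_cache × margin),   margin ≥ 1, default 1.1

computed in decimal arithmetic so an exact product never rounds up a
spurious byte. The 1.1 default buys headroom for the search processes
themselves; observed practice provisions 128 GB machines for ~96 GB
working sets, which a 1.1 margin reproduces. The selector then returns
the minimal-RAM catalog entry with `ram ≥ bytes_needed`, ties broken by
lower hourly price then name — "smallest sufficient" is the published
behaviour; the tie-break order is repo-defined. An explicit
`machine-type` override wins even when oversized, but an undersized
override is rejected.

The bundled catalog is data, not code: it carries the handful of
machines used in the published cost examples (c5ad.4xlarge,
r5ad.4xlarge, r5ad.24xlarge, e2-highmem-8/-16, n1-highmem-96) with
their printed vCPU/RAM/price figures where printed; the remaining
prices are the providers' on-demand rates of the same era. Real
deployments would supply their own JSON/CSV catalog (400+ types per
provider).

## Thread layout

At most 16 threads per search process — beyond that, intra-process
scaling is poor — so an instance with `v` vCPUs runs
`max(1, ⌊v/16⌋)` processes of `min(v, 16)` threads. Databases whose
cached bytes fall below 4 GiB switch to the per-query threading mode,
which amortises better when the database scan is cheap; the 4 GiB
threshold is a repo-set calibration constant (the alternate mode is
documented behaviour, its threshold is not published).

## Batch-length defaults

Defaults aim each job at a 5–30 minute median runtime. No published
table exists, so the defaults are calibration constants: 5,000,000
bases per batch for nucleotide-query programs (blastn, megablast),
20,000 residues for protein/translated programs, halved when the
database's cached bytes reach 50 GiB (each query base does more work),
doubled below 4 GiB, and doubled again for query sets ≥ 100× the base
(to cap job counts). An explicit `batch-len` always wins, which is the
supported tuning path.

## Job lifecycle

States PENDING → RUNNING → {SUCCEEDED, FAILED}, with transitions:

| from | event | to |
|---|---|---|
| PENDING | start | RUNNING (attempts+1) |
| RUNNING | success | SUCCEEDED |
| RUNNING | failure_oom | FAILED (never retried) |
| RUNNING | failure_generic / preempted | PENDING if attempts ≤ 3 else FAILED |

"Up to three times" is read as three retries after the first attempt
(≤ 4 executions), and a preemption-driven restart consumes a retry
slot — whether reclamation shares the retry budget with ordinary
failures is not specified upstream, so the stricter reading was chosen.
Out-of-memory is signalled by the reserved exit code 137 (128+SIGKILL,
what an OOM-killed process actually returns); a wrapper script maps
real kills to it. The shutdown monitor runs every 5 minutes and tears
the run down on all-success or on the first failure; pending jobs are
then cancelled, in-flight results and all previously written result
objects are retained. The local executor requeues retries behind
outstanding work, so a persistently failing batch does not starve its
neighbours.

## Cluster simulator

A heap-based discrete-event loop (seconds internally, hours in
reports) models what the managed batch services do:

- **scaling**: after every event the pool grows toward
  `min(max_nodes, ⌈outstanding/slots⌉)` instances, where `slots` is the
  thread plan's process count; each new instance becomes productive
  `startup_delay` minutes after being requested;
- **preemption**: per-instance Poisson process at
  `preemption_rate_per_hour`; a preempted instance dies, its running
  jobs requeue through the ordinary retry budget, and the scaler
  requests a replacement;
- **scale-down**: an idle instance shuts down after `scale_down_lag`
  minutes (immediately at lag 0 with an empty queue);
- **monitor**: the 5-minute teardown check above;
- **billing**: each instance accrues hours from boot to shutdown in its
  pricing class (on-demand / preemptible).

All randomness flows from one seeded `random.Random`, and heap ties are
broken by insertion order, so runs are exactly reproducible. With zero
overheads and `k` single-slot instances over `k·m` equal jobs the
makespan is exactly `1/k` of the single-instance makespan and billed
hours equal total work; with a nonzero scale-down lag and an
indivisible workload (e.g. 12 one-hour jobs on 8 nodes), the half of
the fleet that idles while the rest finish keeps billing through the
lag, so billed hours strictly exceed the work — the mechanism behind
wide clusters costing more than narrow ones for the same search.

Stale-event correctness: a completion event is honoured only if the job
is still scheduled on that instance *with the same end time*, so a
preempt-and-reassign race cannot complete a job early.

The startup delay is a free parameter (observed values range up to
~20 min, dominated by database download and varying with network and
database size; no formula is published). Kubernetes/Batch wire
behaviour is not emulated — only the scheduling semantics above.

## Cost model

Compute: `hours × n_instances × hourly_price`, multiplied by
`spot_discount` (0.2 for GCP preemptible capacity) when discounted.
When a workload is described by total vCPUs, the instance count is
`⌈total_vcpus / vcpus_per_instance⌉`. Storage: `GB × months × rate`
with rate $0.023/GB-month. Rounding: half-up at 2 decimals for amounts
≥ $0.01; sub-cent amounts at full precision; per-unit figures at 2
significant figures. This convention reproduces every published figure
the test suite asserts.

One published multi-instance cost series is deliberately *not* modeled
as `time × n × rate`: autoscaled runs bill actual instance-hours, which
that arithmetic overstates. The simulator's billing meter is the
supported path for such estimates. Likewise one published vCPU count
(2,481) is not a multiple of the instance size, so its printed cost is
used only as an input constant, never recomputed.

## Synthetic data

`generate_fixture_fasta` draws sequence lengths uniformly from a range
with a fixed seed; `synth_metadata` builds database metadata with
realistic ratios (≈1 byte/residue protein core, ≈0.25 byte/base
nucleotide core, 10–40% index overhead, non-cached files roughly
doubling the on-disk total). The mock search executable emits one
deterministic line per query (id, batch index, CRC32 of the sequence)
and takes a per-batch behaviour script (fail N times, out-of-memory,
arbitrary exit code) with attempt counters persisted across process
invocations. These fixtures exercise the orchestration contracts —
batching, retries, result completeness, teardown — but say nothing
about alignment quality, real BLAST runtimes, or real cloud pricing
drift; passing tests validate the orchestration layer, not search
biology.

## Scale of the shipped checks

The test suite and the acceptance script run at desk scale by design:
50-sequence end-to-end fixtures, 8–12 simulated unit jobs, exhaustive
state-machine enumeration to event-sequence length 6 (~19k sequences),
and 1,000 random splitter instances of ≤ 25 sequences. The published
cloud-scale runs (tens of thousands of vCPUs, hours of wall clock) are
represented by their closed-form cost arithmetic, which is scale-exact.

## Known limitations

- No FASTQ/SRA ingestion; FASTA (plain or gzipped) only.
- One database per search — no cross-instance database sharding.
- No egress, request or inter-region transfer pricing; no live price
  APIs.
- The local executor parallelises with threads around subprocess calls;
  it is I/O-bound plumbing, not a scheduler benchmark.
- Manifest updates are last-writer-wins; concurrent `run` invocations
  on the same manifest are unsupported (detected only for `submit`).
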